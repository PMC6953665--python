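"""Compiled selection vs brute force, two-key sorting, filename find."""

import random
from datetime import datetime, timedelta

import pytest

from trapkit.queries import (Criterion, Query, QueryError, SortKey,
                             compile_query, find_next, select_files,
                             sort_files)
from trapkit.schema import FieldType

from conftest import build_table

# --- independent brute-force oracles ---------------------------------------

def eval_criterion(schema, record, c):
    """Reference semantics, evaluated in pure Python."""
    raw = record.values[c.data_label]
    ftype = schema[c.data_label].field_type
    if ftype in (FieldType.COUNTER, FieldType.UTCOFFSET):
        if raw == "":
            return False
        left, right = float(raw), float(c.value)
    elif ftype is FieldType.DATETIME:
        left, right = raw, c.value
    else:
        if c.operator == "contains":
            return c.value.lower() in raw.lower()
        left, right = raw.lower(), c.value.lower()
    return {"=": left == right, "!=": left != right, "<": left < right,
            "<=": left <= right, ">": left > right,
            ">=": left >= right}[c.operator]


def brute_force_select(table, q):
    keep = all if q.connective == "AND" else any
    return {r.record_id for r in table
            if keep(eval_criterion(table.schema, r, c) for c in q.criteria)}


def brute_force_sort(table, key):
    """Insertion-order-preserving sort via Python's decorate idiom,
    written against the documented semantics only."""
    def typed(rec, label):
        raw = rec.values[label]
        ftype = table.schema[label].field_type
        if raw == "":
            return (0, 0)
        if ftype is FieldType.COUNTER:
            return (1, int(raw))
        if ftype is FieldType.UTCOFFSET:
            return (1, float(raw))
        if ftype is FieldType.DATETIME:
            return (1, raw)
        return (1, raw.casefold())

    recs = list(table.records)
    passes = []
    if key.secondary is not None:
        passes.append((key.secondary, key.secondary_desc))
    passes.append((key.primary, key.primary_desc))
    for label, desc in passes:
        empty = [r for r in recs if r.values[label] == ""]
        rest = [r for r in recs if r.values[label] != ""]
        rest.sort(key=lambda r: typed(r, label)[1], reverse=desc)
        recs = empty + rest
    return [r.record_id for r in recs]


def random_table(schema, rng, n):
    rows = []
    start = datetime(2019, 10, 2) + timedelta(seconds=rng.randrange(10**6))
    for _ in range(n):
        rows.append({
            "GoatCnt": rng.choice(["", "0", "1", "2", "10"]),
            "Hikers": rng.choice(["", "0", "1", "3"]),
            "Weather": rng.choice(["", "Sunny", "Cloudy", "Foggy"]),
            "Analyst": rng.choice(["", "kim", "Kim", "Saul"]),
            "Comments": rng.choice(["", "goat near creek", "nothing"]),
            "Publicity": rng.choice(["true", "false"]),
        })
    table = build_table(schema, rows, start=start,
                        gap_s=rng.choice([1, 60, 600]))
    return table


CRITERIA_POOL = [
    Criterion("GoatCnt", ">", "0"),
    Criterion("GoatCnt", "=", "2"),
    Criterion("GoatCnt", "<=", "1"),
    Criterion("Hikers", ">=", "1"),
    Criterion("Hikers", "!=", "0"),
    Criterion("Weather", "=", "Sunny"),
    Criterion("Weather", "!=", "Cloudy"),
    Criterion("Analyst", "=", "KIM"),
    Criterion("Comments", "contains", "goat"),
    Criterion("File", "contains", "05"),
    Criterion("DateTime", ">", "2019-10-02T00:10:00"),
    Criterion("Publicity", "=", "true"),
]


class TestSelectFiles:
    def test_goats_and_hikers_example(self, table_builder):
        table = table_builder([
            {"GoatCnt": "1", "Hikers": "2"},
            {"GoatCnt": "0", "Hikers": "5"},
            {"GoatCnt": "3", "Hikers": "0"},
            {"GoatCnt": "2", "Hikers": "1"},
            {},
        ])
        q = Query((Criterion("GoatCnt", ">", "0"),
                   Criterion("Hikers", ">", "0")), "AND")
        assert select_files(table, q).ids == {1, 4}
        assert select_files(table, q).ids == brute_force_select(table, q)

    def test_or_is_union_of_single_criteria(self, survey_schema):
        rng = random.Random(5)
        table = random_table(survey_schema, rng, 40)
        c1, c2 = CRITERIA_POOL[0], CRITERIA_POOL[5]
        union = select_files(table, Query((c1,), "AND")).ids | \
            select_files(table, Query((c2,), "AND")).ids
        assert select_files(table, Query((c1, c2), "OR")).ids == union

    def test_adding_and_criterion_never_grows_selection(self, survey_schema):
        rng = random.Random(6)
        table = random_table(survey_schema, rng, 60)
        base = (CRITERIA_POOL[0],)
        sel1 = select_files(table, Query(base, "AND")).ids
        sel2 = select_files(table, Query(base + (CRITERIA_POOL[3],),
                                         "AND")).ids
        assert sel2 <= sel1

    def test_matches_brute_force_on_many_random_tables(self, survey_schema):
        rng = random.Random(2024)
        for _ in range(120):
            table = random_table(survey_schema, rng, rng.randrange(0, 40))
            k = rng.randrange(1, 4)
            q = Query(tuple(rng.sample(CRITERIA_POOL, k)),
                      rng.choice(["AND", "OR"]))
            assert select_files(table, q).ids == \
                brute_force_select(table, q), q

    def test_illegal_operator_type_pairing_rejected(self, survey_schema):
        with pytest.raises(QueryError, match="contains"):
            compile_query(Query((Criterion("GoatCnt", "contains", "1"),)),
                          survey_schema)
        with pytest.raises(QueryError, match="ordering"):
            compile_query(Query((Criterion("Weather", "<", "Sunny"),)),
                          survey_schema)


class TestCompile:
    def test_two_counter_predicates_joined_by_and(self, survey_schema):
        q = Query((Criterion("GoatCnt", ">", "0"),
                   Criterion("Hikers", ">", "0")), "AND")
        where, params = compile_query(q, survey_schema)
        assert where.count("CAST") == 2
        assert " AND " in where and " OR " not in where
        assert params == [0.0, 0.0]

    def test_single_criterion_has_no_connective(self, survey_schema):
        where, _ = compile_query(
            Query((Criterion("Weather", "=", "Sunny"),)), survey_schema)
        assert " AND " not in where and " OR " not in where

    def test_parameterized_never_inlines_values(self, survey_schema):
        where, params = compile_query(
            Query((Criterion("Comments", "contains", "x'); DROP"),)),
            survey_schema)
        assert "DROP" not in where
        assert params == ["x'); DROP"]


class TestSortFiles:
    def test_datetime_sort_recovers_capture_order(self, survey_schema):
        # files named 1.jpg, 10.jpg, 2.jpg sort as strings in that order,
        # but by DateTime they return to capture order
        rows = [{}, {}, {}]
        table = build_table(survey_schema, rows)
        names = ["1.jpg", "10.jpg", "2.jpg"]
        stamps = ["2019-10-02T06:00:00", "2019-10-02T08:00:00",
                  "2019-10-02T07:00:00"]
        for rec, name, ts in zip(table.records, names, stamps):
            rec.values["File"] = name
            rec.values["DateTime"] = ts
        by_name = sort_files(table, SortKey("File"))
        assert [r.values["File"] for r in by_name] == \
            ["1.jpg", "10.jpg", "2.jpg"]
        by_time = sort_files(table, SortKey("DateTime"))
        assert [r.values["File"] for r in by_time] == \
            ["1.jpg", "2.jpg", "10.jpg"]

    def test_single_record_sorts_to_itself(self, table_builder):
        table = table_builder([{"GoatCnt": "5"}])
        assert sort_files(table, SortKey("GoatCnt")).record_ids == [1]

    def test_two_key_sort_matches_brute_force(self, survey_schema):
        rng = random.Random(99)
        for _ in range(60):
            table = random_table(survey_schema, rng, rng.randrange(0, 30))
            fields = rng.sample(["GoatCnt", "Weather", "Analyst",
                                 "DateTime", "Hikers"], 2)
            key = SortKey(fields[0], fields[1],
                          primary_desc=rng.random() < 0.5,
                          secondary_desc=rng.random() < 0.5)
            assert sort_files(table, key).record_ids == \
                brute_force_sort(table, key), key

    def test_sort_is_a_permutation_and_stable(self, survey_schema):
        rng = random.Random(3)
        table = random_table(survey_schema, rng, 50)
        out = sort_files(table, SortKey("Weather"))
        assert sorted(out.record_ids) == sorted(table.record_ids)
        # stability: equal keys keep prior relative order
        by_weather = {}
        for rid in out.record_ids:
            w = table.record(rid).values["Weather"]
            by_weather.setdefault(w, []).append(rid)
        for rids in by_weather.values():
            assert rids == sorted(
                rids, key=lambda r: table.index_of(r))

    def test_empty_values_sort_first(self, table_builder):
        table = table_builder([{"GoatCnt": "4"}, {}, {"GoatCnt": "1"}])
        table.records[1].values["GoatCnt"] = ""
        out = sort_files(table, SortKey("GoatCnt"))
        assert [r.values["GoatCnt"] for r in out] == ["", "1", "4"]

    def test_same_field_twice_rejected(self):
        with pytest.raises(QueryError, match="differ"):
            SortKey("Weather", "Weather")


class TestFindNext:
    @pytest.fixture
    def mixed_table(self, survey_schema):
        table = build_table(survey_schema, [{} for _ in range(6)])
        names = ["Img01.jpg", "Img05.jpg", "clip1.avi", "Img105.jpg",
                 "clip2.AVI", "Img07.jpg"]
        for rec, name in zip(table.records, names):
            rec.values["File"] = name
        return table

    def test_finds_next_name_containing_fragment(self, mixed_table):
        assert find_next(mixed_table, 1, "05") == 2
        assert find_next(mixed_table, 2, "05") == 4

    def test_avi_steps_through_all_videos(self, mixed_table):
        hits = []
        rid = None
        for _ in range(3):
            rid = find_next(mixed_table, rid, ".avi", wrap=False)
            if rid is None:
                break
            hits.append(rid)
        assert hits == [3, 5]  # case-insensitive; stops at the end

    def test_wrap_searches_from_the_top(self, mixed_table):
        assert find_next(mixed_table, 6, "Img01", wrap=True) == 1
        assert find_next(mixed_table, 6, "Img01", wrap=False) is None

    def test_no_match_returns_none(self, mixed_table):
        assert find_next(mixed_table, None, "zebra") is None
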