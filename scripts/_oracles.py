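"""Brute-force reference implementations and random-table builders used by
the acceptance script.  These evaluate the documented semantics directly in
Python, independently of the compiled/SQL code paths they are compared
against."""

from __future__ import annotations

from datetime import datetime, timedelta
from pathlib import Path

from trapkit.queries import Criterion
from trapkit.schema import FieldType, format_datetime, new_record
from trapkit.store import ImageRecord, ImageTable

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


def random_survey_table(schema, rng, n):
    """A plausible hand-entered table over the example survey schema."""
    start = datetime(2019, 10, 2) + timedelta(seconds=rng.randrange(10 ** 6))
    gap = rng.choice([1, 60, 600])
    records = []
    for i in range(n):
        values = new_record(schema)
        values.update({
            "File": f"Img{i + 1:03d}.jpg",
            "RelativePath": "Station1",
            "DateTime": format_datetime(start + timedelta(seconds=i * gap)),
            "GoatCnt": rng.choice(["", "0", "1", "2", "10"]),
            "Hikers": rng.choice(["", "0", "1", "3"]),
            "Weather": rng.choice(["", "Sunny", "Cloudy", "Foggy"]),
            "Analyst": rng.choice(["", "kim", "Kim", "Saul"]),
            "Comments": rng.choice(["", "goat near creek", "nothing"]),
            "Publicity": rng.choice(["true", "false"]),
        })
        records.append(ImageRecord(i + 1, values))
    return ImageTable(schema, records, Path("."))


random_table = random_survey_table


def eval_criterion(schema, record, c):
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
    def typed(rec, label):
        raw = rec.values[label]
        ftype = table.schema[label].field_type
        if ftype is FieldType.COUNTER:
            return int(raw)
        if ftype is FieldType.UTCOFFSET:
            return float(raw)
        if ftype is FieldType.DATETIME:
            return raw
        return raw.casefold()

    recs = list(table.records)
    passes = []
    if key.secondary is not None:
        passes.append((key.secondary, key.secondary_desc))
    passes.append((key.primary, key.primary_desc))
    for label, desc in passes:
        empty = [r for r in recs if r.values[label] == ""]
        rest = [r for r in recs if r.values[label] != ""]
        rest.sort(key=lambda r: typed(r, label), reverse=desc)
        recs = empty + rest
    return [r.record_id for r in recs]
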