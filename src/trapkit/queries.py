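"""Type-aware selection, sorting and filename find over an ImageTable.

Analysts never write SQL; they fill in per-field criteria which are
compiled into a parameterized WHERE clause and run against the record
database (an in-memory SQLite copy of the table).  A query is a flat list
of criteria under a single global AND or OR — no nested boolean trees,
matching the select dialog it models.

Comparison semantics by field type:

* Counter — numeric; a record with an empty (never-entered) counter
  matches no counter criterion.
* DateTime — chronological (the ISO text orders correctly).
* text (Note/Choice/File/...) — case-insensitive; ``contains`` does
  case-insensitive substring match.

Sorting is a stable one- or two-key sort with the same typed comparisons;
records with an empty value in the sort field come first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import sqlite3

from .schema import FieldType, TemplateSchema
from .store import FileSelection, ImageRecord, ImageTable

__all__ = [
    "Criterion",
    "Query",
    "SortKey",
    "compile_query",
    "select_files",
    "sort_files",
    "find_next",
]


class QueryError(ValueError):
    pass


Operator = Literal["=", "!=", "<", "<=", ">", ">=", "contains"]

_ORDERING = ("<", "<=", ">", ">=")
_TEXT_TYPES = (FieldType.NOTE, FieldType.CHOICE, FieldType.FILE,
               FieldType.RELATIVEPATH, FieldType.FOLDER, FieldType.FLAG)


@dataclass(frozen=True)
class Criterion:
    """One per-field constraint, e.g. ``GoatCnt > 0``."""

    data_label: str
    operator: Operator
    value: str

    def __post_init__(self):
        # accept the dialog's mathematical glyphs as aliases
        aliases = {"≠": "!=", "≤": "<=", "≥": ">="}
        if self.operator in aliases:
            object.__setattr__(self, "operator", aliases[self.operator])

    def check_against(self, schema: TemplateSchema) -> FieldType:
        if self.data_label not in schema:
            raise QueryError(f"unknown field {self.data_label!r}")
        ftype = schema[self.data_label].field_type
        if self.operator == "contains":
            if ftype not in (FieldType.NOTE, FieldType.CHOICE,
                             FieldType.FILE):
                raise QueryError(
                    f"'contains' is only legal for Note/Choice/File fields, "
                    f"not {ftype.value}")
        elif self.operator in _ORDERING:
            if ftype not in (FieldType.COUNTER, FieldType.DATETIME,
                             FieldType.UTCOFFSET):
                raise QueryError(
                    f"ordering operator {self.operator!r} is not legal for "
                    f"{ftype.value} fields")
        elif self.operator not in ("=", "!="):
            raise QueryError(f"unknown operator {self.operator!r}")
        return ftype


@dataclass(frozen=True)
class Query:
    """Criteria joined by one global connective."""

    criteria: tuple[Criterion, ...]
    connective: Literal["AND", "OR"] = "AND"

    def __post_init__(self):
        object.__setattr__(self, "criteria", tuple(self.criteria))
        if not self.criteria:
            raise QueryError("a query needs at least one criterion")
        if self.connective not in ("AND", "OR"):
            raise QueryError(f"connective must be AND or OR, "
                             f"got {self.connective!r}")


def _criterion_sql(c: Criterion, ftype: FieldType) -> tuple[str, list]:
    col = f'"{c.data_label}"'
    if ftype in (FieldType.COUNTER, FieldType.UTCOFFSET):
        # empty = never entered: matches nothing numeric
        op = "<>" if c.operator == "!=" else c.operator
        return (f"({col} <> '' AND CAST({col} AS REAL) {op} ?)",
                [float(c.value)])
    if ftype is FieldType.DATETIME:
        op = "<>" if c.operator == "!=" else c.operator
        return f"({col} {op} ?)", [c.value]
    # text semantics, case-insensitive
    if c.operator == "contains":
        return f"(instr(lower({col}), lower(?)) > 0)", [c.value]
    op = "<>" if c.operator == "!=" else "="
    return f"(lower({col}) {op} lower(?))", [c.value]


def compile_query(q: Query, schema: TemplateSchema) -> tuple[str, list]:
    """Compile to a parameterized WHERE clause (text, parameters)."""
    parts, params = [], []
    for c in q.criteria:
        ftype = c.check_against(schema)
        if ftype in (FieldType.COUNTER, FieldType.UTCOFFSET):
            try:
                float(c.value)
            except ValueError:
                raise QueryError(
                    f"{c.data_label}: numeric comparison against "
                    f"non-number {c.value!r}") from None
        sql, p = _criterion_sql(c, ftype)
        parts.append(sql)
        params.extend(p)
    joiner = f" {q.connective} "
    return joiner.join(parts), params


def _table_to_sqlite(table: ImageTable) -> sqlite3.Connection:
    con = sqlite3.connect(":memory:")
    labels = table.schema.data_labels
    cols = ", ".join(f'"{l}" TEXT' for l in labels)
    con.execute(f"CREATE TABLE DataTable (Id INTEGER PRIMARY KEY, {cols})")
    con.executemany(
        "INSERT INTO DataTable VALUES ({})".format(
            ", ".join("?" * (len(labels) + 1))),
        [[r.record_id] + [r.values[l] for l in labels]
         for r in table.records])
    return con


def select_files(table: ImageTable, q: Query) -> FileSelection:
    """Run the compiled query against the table; the matching record ids
    form the selection."""
    where, params = compile_query(q, table.schema)
    con = _table_to_sqlite(table)
    try:
        rows = con.execute(
            f"SELECT Id FROM DataTable WHERE {where}", params).fetchall()
    finally:
        con.close()
    return FileSelection(r[0] for r in rows)


# ---------------------------------------------------------------------------
# Sorting

@dataclass(frozen=True)
class SortKey:
    """One or two sort fields, each ascending or descending."""

    primary: str
    secondary: Optional[str] = None
    primary_desc: bool = False
    secondary_desc: bool = False

    def __post_init__(self):
        if self.secondary is not None and self.secondary == self.primary:
            raise QueryError("primary and secondary sort fields must differ")


def _typed_sort_value(rec: ImageRecord, label: str, ftype: FieldType):
    raw = rec.values[label]
    if raw == "":
        return None
    if ftype is FieldType.COUNTER:
        return int(raw)
    if ftype is FieldType.UTCOFFSET:
        return float(raw)
    if ftype is FieldType.DATETIME:
        return raw  # ISO text sorts chronologically
    return raw.casefold()


def _stable_sort_pass(records: list[ImageRecord], label: str,
                      ftype: FieldType, desc: bool) -> list[ImageRecord]:
    # Empty values always sort first; among the rest, typed order with the
    # requested direction.  Two stable passes keep overall stability.
    nonempty = [r for r in records if r.values[label] != ""]
    empty = [r for r in records if r.values[label] == ""]
    nonempty.sort(key=lambda r: _typed_sort_value(r, label, ftype),
                  reverse=desc)
    return empty + nonempty


def sort_files(table: ImageTable, key: SortKey) -> ImageTable:
    """Stable one- or two-key sort of the presentation order."""
    for label in filter(None, (key.primary, key.secondary)):
        if label not in table.schema:
            raise QueryError(f"unknown sort field {label!r}")
    out = table.copy()
    recs = out.records
    if key.secondary is not None:
        recs = _stable_sort_pass(recs, key.secondary,
                                 table.schema[key.secondary].field_type,
                                 key.secondary_desc)
    recs = _stable_sort_pass(recs, key.primary,
                             table.schema[key.primary].field_type,
                             key.primary_desc)
    out.records = recs
    return out


def find_next(table: ImageTable, from_id: Optional[int], fragment: str,
              wrap: bool = True) -> Optional[int]:
    """The next record (in current order) whose file name contains
    ``fragment``, case-insensitively.

    The search starts after ``from_id`` (or at the first record when
    ``from_id`` is None) and, with ``wrap``, continues from the top back
    to the starting record, which itself is never returned.  Repeated
    calls passing the previous result step through every match.
    """
    recs = table.records
    if not recs:
        return None
    frag = fragment.lower()
    start = 0 if from_id is None else table.index_of(from_id) + 1
    candidates = list(range(start, len(recs)))
    if wrap and from_id is not None:
        candidates += list(range(0, table.index_of(from_id)))
    for i in candidates:
        if frag in recs[i].values["File"].lower():
            return recs[i].record_id
    return None
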