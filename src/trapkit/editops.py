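"""Operators for highly repetitive data entry.

Field notes change slowly from image to image, so most of an analyst's
keystrokes re-enter what they already typed.  These operators cut that
repetition down:

* **propagate** — backfill the last non-empty value over the empty records
  between it and the current image, forward-fill the current value to the
  end, or copy it to every record;
* **copy previous values** — pull all template-flagged *copyable* fields
  from the preceding record;
* **QuickPaste** — a named multi-field assignment pattern applied to the
  current record in one action;
* **text prediction** — complete a Note from its history of previously
  committed entries (most recent match wins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from .schema import FieldType, TemplateSchema, validate_value
from .store import ImageTable

__all__ = [
    "QuickPasteEntry",
    "PredictionHistory",
    "propagate_field",
    "copy_previous_values",
    "apply_quickpaste",
    "predict_text",
    "save_quickpaste",
    "load_quickpaste",
]


class EditOpError(ValueError):
    pass


# Fields that propagation / quickpaste / copy-previous may never touch.
_PROTECTED = ("File", "RelativePath", "DateTime", "UtcOffset")


def _check_editable(schema: TemplateSchema, data_label: str) -> None:
    if data_label not in schema:
        raise EditOpError(f"unknown field {data_label!r}")
    if data_label in _PROTECTED:
        raise EditOpError(f"{data_label!r} is system-maintained")


def propagate_field(table: ImageTable, current_id: int, data_label: str,
                    mode: Literal["backfill", "forward", "all"]) -> ImageTable:
    """Spread one field's value across the presentation order.

    ``backfill`` finds the last non-empty value at a record *before* the
    current one and writes it into every *empty* record between the two,
    and into the current record unconditionally.  ``forward`` overwrites
    the field from the current record to the end with the current value;
    ``all`` overwrites every record.  Forward/all require the current
    value to be non-empty.
    """
    _check_editable(table.schema, data_label)
    k = table.index_of(current_id)
    out = table.copy()
    recs = out.records
    if mode == "backfill":
        source = None
        for i in range(k - 1, -1, -1):
            if recs[i].values[data_label] != "":
                source = i
                break
        if source is None:
            raise EditOpError(
                f"backfill: no earlier non-empty value in {data_label!r}")
        value = recs[source].values[data_label]
        for i in range(source + 1, k):
            if recs[i].values[data_label] == "":
                recs[i].values[data_label] = value
        recs[k].values[data_label] = value
    elif mode in ("forward", "all"):
        value = recs[k].values[data_label]
        if value == "":
            raise EditOpError(f"{mode}: current {data_label!r} is empty")
        targets = recs[k:] if mode == "forward" else recs
        for rec in targets:
            rec.values[data_label] = value
    else:
        raise EditOpError(f"unknown mode {mode!r}")
    return out


def copy_previous_values(table: ImageTable, current_id: int) -> ImageTable:
    """Copy every *copyable* field of the preceding record into the
    current one; all other fields stay untouched.  Idempotent; errors on
    the first record."""
    k = table.index_of(current_id)
    if k == 0:
        raise EditOpError("first record has no predecessor")
    out = table.copy()
    prev, cur = out.records[k - 1], out.records[k]
    for spec in out.schema.fields:
        if spec.copyable and spec.data_label not in _PROTECTED:
            cur.values[spec.data_label] = prev.values[spec.data_label]
    return out


@dataclass(frozen=True)
class QuickPasteEntry:
    """A titled, reusable data-entry pattern over several user fields."""

    title: str
    assignments: dict[str, str]

    def check_against(self, schema: TemplateSchema) -> None:
        for label, raw in self.assignments.items():
            if label not in schema:
                raise EditOpError(
                    f"quickpaste {self.title!r}: field {label!r} is not in "
                    "the schema (stale entry?)")
            if label in _PROTECTED:
                raise EditOpError(
                    f"quickpaste {self.title!r}: {label!r} is "
                    "system-maintained")
            validate_value(schema[label], raw)


def apply_quickpaste(table: ImageTable, current_id: int,
                     entry: QuickPasteEntry) -> ImageTable:
    """Paste the entry's assignments into the current record; every other
    field and record is bit-identical."""
    entry.check_against(table.schema)
    k = table.index_of(current_id)
    out = table.copy()
    out.records[k].values.update(entry.assignments)
    return out


def save_quickpaste(entries: list[QuickPasteEntry], path: str | Path) -> Path:
    """Persist entries as JSON beside the database, so a session resumes
    with its patterns intact."""
    path = Path(path)
    doc = [{"title": e.title, "assignments": dict(e.assignments)}
           for e in entries]
    path.write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n",
                    encoding="utf-8")
    return path


def load_quickpaste(path: str | Path) -> list[QuickPasteEntry]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [QuickPasteEntry(e["title"], dict(e["assignments"])) for e in doc]


@dataclass
class PredictionHistory:
    """Per-Note-field history of committed entries, most recent last."""

    schema: TemplateSchema
    entries: dict[str, list[str]] = field(default_factory=dict)

    def commit(self, data_label: str, text: str) -> None:
        """Record a committed entry (Note fields only; empties ignored)."""
        if self.schema[data_label].field_type is not FieldType.NOTE:
            raise EditOpError(f"{data_label!r} is not a Note field")
        if text:
            self.entries.setdefault(data_label, []).append(text)


def predict_text(history: PredictionHistory, data_label: str,
                 prefix: str) -> str | None:
    """The most recently committed value whose start matches ``prefix``
    case-insensitively; None when nothing matches or the prefix is empty."""
    if not prefix:
        return None
    low = prefix.lower()
    for candidate in reversed(history.entries.get(data_label, [])):
        if candidate.lower().startswith(low):
            return candidate
    return None
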