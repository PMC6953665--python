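"""Project data schema: typed field specifications and value validation.

A camera-trap project is driven by a *template*: an ordered list of field
specifications that defines, per image, which data the analyst records and
what each field may contain.  Four standard fields (``File``,
``RelativePath``, ``DateTime``, ``UtcOffset``) are always present and are
maintained by the system rather than typed in by the analyst; user-defined
fields (counts, choices, free-text notes, flags) follow them in template
order, which is also the column order of every exported table.

Field types and their storage rules:

``Note``
    Free-form text.  Empty means "not yet entered".
``Choice``
    Text constrained to an ordered list of allowed values; empty allowed.
``Counter``
    A non-negative base-10 integer, stored as text.  Zero is a legal count
    (recording the *absence* of an entity is routine).
``Flag``
    Exactly ``"true"`` or ``"false"`` (case-insensitive on input, stored
    lowercase).
``DateTime``
    ISO-8601 ``YYYY-MM-DDTHH:MM:SS`` with a four-digit year; second
    resolution.
``UtcOffset``
    Signed decimal hours in [-14, +14], e.g. ``-7`` or ``5.5``.
``File`` / ``RelativePath`` / ``Folder``
    Path components; any text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Union

__all__ = [
    "FieldType",
    "FieldSpec",
    "TemplateSchema",
    "ValidatedValue",
    "SchemaError",
    "ValidationError",
    "STANDARD_LABELS",
    "make_schema",
    "is_valid",
    "parse_template",
    "write_template",
    "validate_value",
    "new_record",
    "parse_datetime",
    "format_datetime",
]

DATETIME_FORMAT = "%Y-%m-%dT%H:%M:%S"
_DATETIME_RE = re.compile(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}$")
_COLUMN_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class SchemaError(ValueError):
    """A template or field specification violates a structural rule."""


class ValidationError(ValueError):
    """A raw value was rejected; ``rule`` names the violated constraint."""

    def __init__(self, message: str, rule: str):
        super().__init__(message)
        self.rule = rule


class FieldType(str, Enum):
    NOTE = "Note"
    CHOICE = "Choice"
    COUNTER = "Counter"
    FLAG = "Flag"
    DATETIME = "DateTime"
    UTCOFFSET = "UtcOffset"
    FILE = "File"
    RELATIVEPATH = "RelativePath"
    FOLDER = "Folder"


#: data_label -> field type of the four system-maintained fields, in the
#: fixed order they occupy at the head of every schema.
STANDARD_FIELDS: dict[str, FieldType] = {
    "File": FieldType.FILE,
    "RelativePath": FieldType.RELATIVEPATH,
    "DateTime": FieldType.DATETIME,
    "UtcOffset": FieldType.UTCOFFSET,
}
STANDARD_LABELS = tuple(STANDARD_FIELDS)

# Field types whose empty string means "not yet entered".
_EMPTY_OK = {FieldType.NOTE, FieldType.CHOICE, FieldType.COUNTER,
             FieldType.FILE, FieldType.RELATIVEPATH, FieldType.FOLDER}


@dataclass(frozen=True)
class FieldSpec:
    """One column of the per-image data record.

    Parameters
    ----------
    field_type:
        Storage/validation type of the field.
    data_label:
        Database column name; must be a legal SQL identifier, unique
        within the schema.
    label:
        Analyst-facing control name (e.g. ``"Goats"`` for ``GoatCnt``).
        Defaults to ``data_label``.
    tooltip:
        Help text shown to the analyst.
    default_value:
        Value every freshly scanned image starts with; must itself
        validate against ``field_type``.
    choice_list:
        Allowed values, in menu order.  Required for ``Choice`` fields
        and forbidden otherwise.
    visible:
        Whether the control is shown to the analyst.
    copyable:
        Whether the copy-previous-values operation includes this field.
    """

    field_type: FieldType
    data_label: str
    label: str = ""
    tooltip: str = ""
    default_value: str = ""
    choice_list: tuple[str, ...] = ()
    visible: bool = True
    copyable: bool = False

    def __post_init__(self):
        if not self.data_label:
            raise SchemaError("data_label must be non-empty")
        if not _COLUMN_RE.match(self.data_label):
            raise SchemaError(
                f"data_label {self.data_label!r} is not a legal column name")
        if not isinstance(self.field_type, FieldType):
            object.__setattr__(self, "field_type", FieldType(self.field_type))
        object.__setattr__(self, "choice_list", tuple(self.choice_list))
        if not self.label:
            object.__setattr__(self, "label", self.data_label)
        if self.field_type is FieldType.CHOICE:
            if not self.choice_list:
                raise SchemaError(
                    f"Choice field {self.data_label!r} needs a choice list")
        elif self.choice_list:
            raise SchemaError(
                f"field {self.data_label!r}: only Choice fields take a list")
        # Types with no meaningful "not yet entered" state get a concrete
        # default so that a fresh record always validates.
        if not self.default_value:
            if self.field_type is FieldType.FLAG:
                object.__setattr__(self, "default_value", "false")
            elif self.field_type is FieldType.DATETIME:
                object.__setattr__(self, "default_value", "1900-01-01T00:00:00")
            elif self.field_type is FieldType.UTCOFFSET:
                object.__setattr__(self, "default_value", "0")
        validate_value(self, self.default_value)

    @property
    def is_standard(self) -> bool:
        return self.data_label in STANDARD_FIELDS

    @property
    def analyst_editable(self) -> bool:
        """UtcOffset aside, standard fields change only via scan/time repair."""
        return self.data_label not in ("File", "RelativePath", "DateTime")


@dataclass(frozen=True)
class TemplateSchema:
    """Ordered field specifications; standard fields first, exactly once."""

    fields: tuple[FieldSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "fields", tuple(self.fields))
        labels = [f.data_label for f in self.fields]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise SchemaError(f"duplicate data_label(s): {sorted(dupes)}")
        for name, ftype in STANDARD_FIELDS.items():
            matches = [f for f in self.fields if f.data_label == name]
            if len(matches) != 1:
                raise SchemaError(f"schema must contain exactly one {name!r}")
            if matches[0].field_type is not ftype:
                raise SchemaError(
                    f"standard field {name!r} must have type {ftype.value}")
        head = labels[: len(STANDARD_FIELDS)]
        if head != list(STANDARD_FIELDS):
            raise SchemaError(
                "standard fields must come first in the order "
                f"{list(STANDARD_FIELDS)}; got {head}")

    @property
    def data_labels(self) -> list[str]:
        return [f.data_label for f in self.fields]

    @property
    def user_fields(self) -> list[FieldSpec]:
        return [f for f in self.fields if not f.is_standard]

    def __getitem__(self, data_label: str) -> FieldSpec:
        for f in self.fields:
            if f.data_label == data_label:
                return f
        raise KeyError(data_label)

    def __contains__(self, data_label: str) -> bool:
        return any(f.data_label == data_label for f in self.fields)


def _standard_specs() -> list[FieldSpec]:
    return [
        FieldSpec(FieldType.FILE, "File", tooltip="The file's name"),
        FieldSpec(FieldType.RELATIVEPATH, "RelativePath",
                  tooltip="Path from the image-set root to the file"),
        FieldSpec(FieldType.DATETIME, "DateTime",
                  default_value="1900-01-01T00:00:00",
                  tooltip="Date and time the image was taken"),
        FieldSpec(FieldType.UTCOFFSET, "UtcOffset", default_value="0",
                  tooltip="Offset of local time from UTC, in hours"),
    ]


def make_schema(user_fields: list[FieldSpec] = ()) -> TemplateSchema:
    """Build a schema from user fields, prepending the standard fields."""
    return TemplateSchema(tuple(_standard_specs()) + tuple(user_fields))


@dataclass(frozen=True)
class ValidatedValue:
    """A raw text value together with its typed interpretation."""

    data_label: str
    raw: str
    typed: Union[str, int, bool, datetime, float, None]


def parse_datetime(raw: str) -> datetime:
    """Parse the canonical timestamp text; four-digit years only."""
    if not _DATETIME_RE.match(raw):
        raise ValidationError(
            f"{raw!r} is not a YYYY-MM-DDTHH:MM:SS timestamp", rule="format")
    try:
        return datetime.strptime(raw, DATETIME_FORMAT)
    except ValueError as exc:
        raise ValidationError(f"{raw!r}: {exc}", rule="format") from None


def format_datetime(dt: datetime) -> str:
    return dt.strftime(DATETIME_FORMAT)


def validate_value(spec: FieldSpec, raw: str) -> ValidatedValue:
    """Check ``raw`` against the field's type rules.

    Returns the :class:`ValidatedValue` on acceptance and raises
    :class:`ValidationError` (carrying the violated ``rule``) otherwise.
    An empty string is accepted, as "not yet entered", for Note, Choice,
    Counter and path-like fields.
    """
    if not isinstance(raw, str):
        raise ValidationError(f"{spec.data_label}: value must be text",
                              rule="type")
    ftype = spec.field_type
    if raw == "":
        if ftype in _EMPTY_OK:
            return ValidatedValue(spec.data_label, raw, None)
        raise ValidationError(
            f"{spec.data_label}: empty value not allowed for {ftype.value}",
            rule="type")

    if ftype in (FieldType.NOTE, FieldType.FILE, FieldType.RELATIVEPATH,
                 FieldType.FOLDER):
        return ValidatedValue(spec.data_label, raw, raw)
    if ftype is FieldType.CHOICE:
        if raw not in spec.choice_list:
            raise ValidationError(
                f"{spec.data_label}: {raw!r} is not one of "
                f"{list(spec.choice_list)}", rule="not-in-list")
        return ValidatedValue(spec.data_label, raw, raw)
    if ftype is FieldType.COUNTER:
        if not raw.isascii() or not raw.isdigit():
            raise ValidationError(
                f"{spec.data_label}: counters take a non-negative integer, "
                f"got {raw!r}", rule="type")
        return ValidatedValue(spec.data_label, raw, int(raw))
    if ftype is FieldType.FLAG:
        low = raw.lower()
        if low not in ("true", "false"):
            raise ValidationError(
                f"{spec.data_label}: flags store 'true' or 'false', "
                f"got {raw!r}", rule="type")
        return ValidatedValue(spec.data_label, raw, low == "true")
    if ftype is FieldType.DATETIME:
        return ValidatedValue(spec.data_label, raw, parse_datetime(raw))
    if ftype is FieldType.UTCOFFSET:
        try:
            hours = float(raw)
        except ValueError:
            raise ValidationError(
                f"{spec.data_label}: UTC offset must be decimal hours, "
                f"got {raw!r}", rule="format") from None
        if not -14.0 <= hours <= 14.0:
            raise ValidationError(
                f"{spec.data_label}: UTC offset {hours} outside [-14, 14]",
                rule="range")
        return ValidatedValue(spec.data_label, raw, hours)
    raise AssertionError(f"unhandled field type {ftype}")  # pragma: no cover


def is_valid(spec: FieldSpec, raw: str) -> bool:
    try:
        validate_value(spec, raw)
    except ValidationError:
        return False
    return True


def new_record(schema: TemplateSchema) -> dict[str, str]:
    """A fresh record: every field initialised to its default value."""
    return {f.data_label: f.default_value for f in schema.fields}


# ---------------------------------------------------------------------------
# Template persistence.  Templates are stored as JSON with a fixed key order
# so that equal schemas serialize to byte-identical files.

TEMPLATE_VERSION = "1"
_FIELD_KEYS = ("type", "data_label", "label", "tooltip", "default",
               "list", "visible", "copyable")


def _spec_to_json(spec: FieldSpec) -> dict:
    return {
        "type": spec.field_type.value,
        "data_label": spec.data_label,
        "label": spec.label,
        "tooltip": spec.tooltip,
        "default": spec.default_value,
        "list": list(spec.choice_list),
        "visible": spec.visible,
        "copyable": spec.copyable,
    }


def _spec_from_json(obj: dict, index: int) -> FieldSpec:
    if not isinstance(obj, dict):
        raise SchemaError(f"field #{index}: expected an object")
    unknown = set(obj) - set(_FIELD_KEYS)
    if unknown:
        raise SchemaError(f"field #{index}: unknown key(s) {sorted(unknown)}")
    try:
        ftype = FieldType(obj.get("type", ""))
    except ValueError:
        raise SchemaError(
            f"field #{index} ({obj.get('data_label', '?')!r}): "
            f"unknown type {obj.get('type')!r}") from None
    try:
        return FieldSpec(
            field_type=ftype,
            data_label=obj.get("data_label", ""),
            label=obj.get("label", ""),
            tooltip=obj.get("tooltip", ""),
            default_value=obj.get("default", ""),
            choice_list=tuple(obj.get("list", ())),
            visible=bool(obj.get("visible", True)),
            copyable=bool(obj.get("copyable", False)),
        )
    except (SchemaError, ValidationError) as exc:
        raise SchemaError(
            f"field #{index} ({obj.get('data_label', '?')!r}): {exc}") from exc


def parse_template(path: str | Path) -> TemplateSchema:
    """Load a template JSON file.

    Standard fields absent from the file are inserted with their defaults;
    user fields keep file order.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed template JSON: {exc}") from exc
    if not isinstance(doc, dict) or "fields" not in doc:
        raise SchemaError(f"{path}: template must be an object with 'fields'")
    specs = [_spec_from_json(obj, i) for i, obj in enumerate(doc["fields"])]
    by_label: dict[str, FieldSpec] = {}
    for s in specs:
        if s.data_label in by_label:
            raise SchemaError(f"{path}: duplicate data_label {s.data_label!r}")
        by_label[s.data_label] = s
    standard = [by_label.pop(name, default)
                for name, default in zip(STANDARD_FIELDS,
                                         _standard_specs())]
    user = [s for s in specs if s.data_label in by_label]
    return TemplateSchema(tuple(standard) + tuple(user))


def write_template(schema: TemplateSchema, path: str | Path) -> Path:
    """Serialize deterministically: fixed key order, 2-space indent, LF."""
    path = Path(path)
    doc = {"version": TEMPLATE_VERSION,
           "fields": [_spec_to_json(f) for f in schema.fields]}
    text = json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
    path.write_text(text, encoding="utf-8", newline="\n")
    return path
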