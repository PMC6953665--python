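"""Per-image record database: scanning, editing, CSV and SQLite exchange.

The unit of work is an :class:`ImageTable`: one record per image file under
a root folder, with one value (stored as text) per schema field.  Scanning
fills the standard fields from the file system and EXIF; analysts then fill
the user fields, usually in bulk.  The table round-trips through CSV
(RFC 4180 quoting, UTF-8, LF newlines) and persists in a single-file SQLite
database whose one data table has exactly the schema's columns.

Counter fields may additionally carry *markers*: normalized (x, y) points,
one per counted entity, recorded when the analyst clicks entities in the
image.  Markers are stored here (and in an auxiliary SQLite table) but
never rendered.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator

from . import schema as _schema
from .schema import (FieldType, TemplateSchema, ValidationError,
                     format_datetime, new_record, validate_value)

__all__ = [
    "ImageRecord",
    "ImageTable",
    "FileSelection",
    "DIFFERS",
    "IMAGE_EXTENSIONS",
    "VIDEO_EXTENSIONS",
    "scan_image_set",
    "set_field",
    "summarize_selection",
    "export_csv",
    "import_csv",
    "save_database",
    "load_database",
]

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".jpg", ".jpeg", ".png")
VIDEO_EXTENSIONS = (".avi", ".mp4")

#: Sentinel returned by :func:`summarize_selection` when values differ.
DIFFERS = "…"  # the ellipsis the analyst sees


class StoreError(ValueError):
    pass


@dataclass
class ImageRecord:
    """One image's data: a record id plus data_label -> raw text."""

    record_id: int
    values: dict[str, str]
    #: True when DateTime came from EXIF rather than file modification time.
    datetime_from_exif: bool = False

    def copy(self) -> "ImageRecord":
        return ImageRecord(self.record_id, dict(self.values),
                           self.datetime_from_exif)


@dataclass
class ImageTable:
    """Ordered records under one schema, rooted at an image-set folder."""

    schema: TemplateSchema
    records: list[ImageRecord] = field(default_factory=list)
    root: Path = Path(".")
    #: (record_id, counter data_label) -> list of normalized (x, y) points.
    markers: dict[tuple[int, str], list[tuple[float, float]]] = field(
        default_factory=dict)
    #: Chronological log of applied bulk operations (see trapkit.timefix).
    audit: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self._check_ids()

    def _check_ids(self):
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise StoreError("record_ids must be unique")
        paths = [(r.values.get("RelativePath", ""), r.values.get("File", ""))
                 for r in self.records]
        if len(paths) != len(set(paths)):
            raise StoreError("(RelativePath, File) pairs must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    @property
    def record_ids(self) -> list[int]:
        return [r.record_id for r in self.records]

    def record(self, record_id: int) -> ImageRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(f"no record with id {record_id}")

    def index_of(self, record_id: int) -> int:
        for i, r in enumerate(self.records):
            if r.record_id == record_id:
                return i
        raise KeyError(f"no record with id {record_id}")

    def next_record_id(self) -> int:
        return max((r.record_id for r in self.records), default=0) + 1

    def copy(self) -> "ImageTable":
        t = ImageTable(self.schema, [r.copy() for r in self.records],
                       self.root,
                       {k: list(v) for k, v in self.markers.items()},
                       [dict(a) for a in self.audit])
        return t

    def validate(self) -> None:
        """Raise if any stored value violates its field's type rules."""
        for r in self.records:
            for spec in self.schema.fields:
                if spec.data_label not in r.values:
                    raise StoreError(
                        f"record {r.record_id} missing {spec.data_label!r}")
                validate_value(spec, r.values[spec.data_label])

    def add_marker(self, record_id: int, data_label: str,
                   x: float, y: float) -> None:
        """Record a counted entity's normalized image position."""
        if self.schema[data_label].field_type is not FieldType.COUNTER:
            raise StoreError(f"{data_label!r} is not a Counter field")
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise StoreError("marker coordinates must lie in [0, 1]")
        self.record(record_id)  # existence check
        self.markers.setdefault((record_id, data_label), []).append((x, y))


@dataclass(frozen=True)
class FileSelection:
    """A subset of a table's records, by record id."""

    ids: frozenset[int]

    def __init__(self, ids: Iterable[int]):
        object.__setattr__(self, "ids", frozenset(ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, record_id: int) -> bool:
        return record_id in self.ids

    def check_against(self, table: ImageTable) -> None:
        extra = self.ids - set(table.record_ids)
        if extra:
            raise StoreError(f"selection ids not in table: {sorted(extra)}")


# ---------------------------------------------------------------------------
# Scanning

def scan_image_set(root: str | Path, schema: TemplateSchema,
                   existing: ImageTable | None = None) -> ImageTable:
    """Build (or refresh) the record table from the files under ``root``.

    One record is created per image or video file, with the standard fields
    filled in: ``File`` is the file name, ``RelativePath`` the forward-slash
    path of its folder relative to the root, and ``DateTime`` the EXIF
    ``DateTimeOriginal`` when present, else the file's modification time.
    User fields start at their template defaults.  Traversal order is
    lexicographic by (RelativePath, File).

    Re-scanning with ``existing`` keeps already-entered values for files
    that are still present and only appends records for new files.
    """
    from .metadata import read_exif_datetime  # cycle-free local import

    root = Path(root)
    if not root.is_dir():
        raise StoreError(f"image-set root {root} does not exist")

    known: dict[tuple[str, str], ImageRecord] = {}
    if existing is not None:
        known = {(r.values["RelativePath"], r.values["File"]): r
                 for r in existing.records}

    entries = []
    for p in root.rglob("*"):
        if not p.is_file():
            continue
        ext = p.suffix.lower()
        if ext not in IMAGE_EXTENSIONS + VIDEO_EXTENSIONS:
            continue
        rel = p.parent.relative_to(root).as_posix()
        rel = "" if rel == "." else rel
        entries.append((rel, p.name, p))
    entries.sort(key=lambda e: (e[0], e[1]))

    table = ImageTable(schema, [], root)
    if existing is not None:
        table.markers = {k: list(v) for k, v in existing.markers.items()}
        table.audit = [dict(a) for a in existing.audit]
    next_id = (existing.next_record_id() if existing is not None else 1)
    for rel, name, p in entries:
        prior = known.get((rel, name))
        if prior is not None:
            table.records.append(prior.copy())
            continue
        values = new_record(schema)
        values["File"] = name
        values["RelativePath"] = rel
        from_exif = False
        dt = None
        if p.suffix.lower() in IMAGE_EXTENSIONS:
            try:
                dt = read_exif_datetime(p)
            except Exception as exc:  # unreadable file: fall back, warn
                logger.warning("could not read %s: %s", p, exc)
        if dt is not None:
            from_exif = True
        else:
            dt = datetime.fromtimestamp(p.stat().st_mtime).replace(
                microsecond=0)
        values["DateTime"] = format_datetime(dt)
        table.records.append(ImageRecord(next_id, values, from_exif))
        next_id += 1
    table._check_ids()
    return table


# ---------------------------------------------------------------------------
# Editing

def set_field(table: ImageTable, sel: FileSelection, data_label: str,
              raw: str) -> ImageTable:
    """Write one validated value into every selected record (bulk edit).

    The value is validated once; on failure no record changes.  The
    system-maintained fields File, RelativePath and DateTime cannot be set
    this way (DateTime changes only through the time-repair operations).
    """
    if data_label not in table.schema:
        raise StoreError(f"unknown field {data_label!r}")
    spec = table.schema[data_label]
    if not spec.analyst_editable:
        raise StoreError(f"{data_label!r} is not analyst-editable")
    sel.check_against(table)
    validate_value(spec, raw)
    out = table.copy()
    for r in out.records:
        if r.record_id in sel:
            r.values[data_label] = raw
    return out


def summarize_selection(table: ImageTable, sel: FileSelection,
                        data_label: str) -> str:
    """The selection's common value for a field, or :data:`DIFFERS`."""
    if len(sel) == 0:
        raise StoreError("empty selection")
    sel.check_against(table)
    if data_label not in table.schema:
        raise StoreError(f"unknown field {data_label!r}")
    vals = {r.values[data_label] for r in table.records if r.record_id in sel}
    return vals.pop() if len(vals) == 1 else DIFFERS


# ---------------------------------------------------------------------------
# CSV exchange

def export_csv(table: ImageTable, path: str | Path) -> Path:
    """Write the table: header = data_labels in schema order, LF newlines."""
    path = Path(path)
    labels = table.schema.data_labels
    with io.StringIO() as buf:
        writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL,
                            lineterminator="\n")
        writer.writerow(labels)
        for r in table.records:
            writer.writerow([r.values[l] for l in labels])
        path.write_text(buf.getvalue(), encoding="utf-8", newline="")
    return path


def import_csv(path: str | Path, schema: TemplateSchema,
               root: str | Path = ".") -> ImageTable:
    """Read a CSV whose header holds exactly the schema's labels (any order).

    Every cell is validated against its field; the first offending
    row/column is named in the error.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StoreError(f"{path}: empty file") from None
        unknown = [c for c in header if c not in schema]
        if unknown:
            raise StoreError(f"{path}: unknown column(s) {unknown}")
        missing = [l for l in schema.data_labels if l not in header]
        if missing:
            raise StoreError(f"{path}: missing column(s) {missing}")
        if len(set(header)) != len(header):
            raise StoreError(f"{path}: duplicate column in header")
        table = ImageTable(schema, [], Path(root))
        for row_no, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise StoreError(f"{path}: row {row_no} has {len(row)} cells,"
                                 f" expected {len(header)}")
            values = dict(zip(header, row))
            for label, raw in values.items():
                try:
                    validate_value(schema[label], raw)
                except ValidationError as exc:
                    raise StoreError(
                        f"{path}: row {row_no}, column {label!r}: {exc}"
                    ) from exc
            table.records.append(ImageRecord(row_no - 1, values))
        table._check_ids()
    return table


# ---------------------------------------------------------------------------
# SQLite persistence.  One file holds the data table (columns exactly the
# schema's data_labels plus Id), the template itself, counter markers and
# the audit log, so a saved database is self-describing.

def save_database(table: ImageTable, path: str | Path) -> Path:
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        labels = table.schema.data_labels
        cols = ", ".join(f'"{l}" TEXT NOT NULL' for l in labels)
        con.execute(f"CREATE TABLE DataTable (Id INTEGER PRIMARY KEY, {cols})")
        con.executemany(
            "INSERT INTO DataTable VALUES ({})".format(
                ", ".join("?" * (len(labels) + 1))),
            [[r.record_id] + [r.values[l] for l in labels]
             for r in table.records])
        con.execute("CREATE TABLE Meta (key TEXT PRIMARY KEY, value TEXT)")
        tmpl = {"version": _schema.TEMPLATE_VERSION,
                "fields": [_schema._spec_to_json(f)
                           for f in table.schema.fields]}
        con.execute("INSERT INTO Meta VALUES ('template', ?)",
                    (json.dumps(tmpl),))
        con.execute("INSERT INTO Meta VALUES ('root', ?)",
                    (str(table.root),))
        con.execute("CREATE TABLE Markers (record_id INTEGER, "
                    "data_label TEXT, x REAL, y REAL)")
        con.executemany(
            "INSERT INTO Markers VALUES (?, ?, ?, ?)",
            [(rid, label, x, y)
             for (rid, label), pts in table.markers.items()
             for (x, y) in pts])
        con.execute("CREATE TABLE AuditLog (seq INTEGER PRIMARY KEY, "
                    "entry TEXT)")
        con.executemany("INSERT INTO AuditLog VALUES (?, ?)",
                        [(i, json.dumps(a))
                         for i, a in enumerate(table.audit)])
        con.commit()
    finally:
        con.close()
    return path


def load_database(path: str | Path) -> ImageTable:
    path = Path(path)
    if not path.exists():
        raise StoreError(f"no database at {path}")
    con = sqlite3.connect(path)
    try:
        tmpl = json.loads(con.execute(
            "SELECT value FROM Meta WHERE key='template'").fetchone()[0])
        specs = [_schema._spec_from_json(obj, i)
                 for i, obj in enumerate(tmpl["fields"])]
        sch = TemplateSchema(tuple(specs))
        root = Path(con.execute(
            "SELECT value FROM Meta WHERE key='root'").fetchone()[0])
        labels = sch.data_labels
        quoted = ", ".join(f'"{l}"' for l in labels)
        rows = con.execute(
            f"SELECT Id, {quoted} FROM DataTable ORDER BY rowid").fetchall()
        table = ImageTable(sch, [], root)
        for row in rows:
            table.records.append(
                ImageRecord(row[0], dict(zip(labels, row[1:]))))
        for rid, label, x, y in con.execute(
                "SELECT record_id, data_label, x, y FROM Markers"):
            table.markers.setdefault((rid, label), []).append((x, y))
        table.audit = [json.loads(e) for (e,) in con.execute(
            "SELECT entry FROM AuditLog ORDER BY seq")]
        table._check_ids()
    finally:
        con.close()
    return table
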