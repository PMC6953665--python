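"""Image metadata: enumerate EXIF tags and bulk-populate a schema field.

Camera vendors embed a mix of standard EXIF tags and proprietary ones; a
trap camera's maker note frequently carries station readings such as the
ambient temperature.  This module exposes everything text-representable as
a flat name -> value map, and can copy one chosen key into a Note field of
every record in a table (the "populate" action of a metadata viewer).

Vendor tag names vary between cameras ("Ambient Temperature" vs
"Temperature C"), so keys are matched by exact string only — the analyst
picks the right key per camera; no fuzzy matching is attempted.  Maker
notes are decoded only when they contain plain ``key=value`` text lines
(the dialect our synthetic generator writes); opaque binary maker notes
are skipped.
"""

from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path

from PIL import ExifTags, Image

from .schema import FieldType
from .store import ImageTable

__all__ = ["list_metadata", "populate_from_metadata", "read_exif_datetime"]

logger = logging.getLogger(__name__)

_EXIF_DATETIME_FORMAT = "%Y:%m:%d %H:%M:%S"
_DATETIME_ORIGINAL = 36867
_MAKER_NOTE = 37500


def _decode(value) -> str | None:
    """Render a tag value as text; None for non-text-representable ones."""
    if isinstance(value, bytes):
        try:
            text = value.decode("utf-8")
        except UnicodeDecodeError:
            return None
        return text if text.isprintable() or "\n" in text else None
    if isinstance(value, (str, int, float)):
        return str(value)
    if isinstance(value, tuple):
        return ", ".join(str(v) for v in value)
    return None


def _maker_note_entries(raw: bytes) -> dict[str, str]:
    """Parse a text maker note of ``key=value`` lines; {} if binary."""
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        return {}
    entries = {}
    for line in text.splitlines():
        if "=" not in line:
            return {}
        key, _, val = line.partition("=")
        if not key.strip():
            return {}
        entries[key.strip()] = val.strip()
    return entries


def list_metadata(image: str | Path) -> dict[str, str]:
    """All text-decodable metadata of ``image`` as tag-name -> value.

    Standard EXIF tags are named per the EXIF specification
    (``DateTimeOriginal``, ``Model``, ...); unnamed tags appear as
    ``Tag<number>``.  Maker-note ``key=value`` lines contribute their keys
    directly.  An unreadable or metadata-free file yields an empty map
    (with a logged warning when unreadable).
    """
    image = Path(image)
    try:
        with Image.open(image) as im:
            exif = im.getexif()
            ifds = [dict(exif)]
            try:
                ifds.append(dict(exif.get_ifd(ExifTags.IFD.Exif)))
            except KeyError:
                pass
    except Exception as exc:
        logger.warning("cannot read metadata from %s: %s", image, exc)
        return {}

    out: dict[str, str] = {}
    for ifd in ifds:
        for tag_id, value in ifd.items():
            if tag_id == ExifTags.IFD.Exif:
                continue
            if tag_id == _MAKER_NOTE and isinstance(value, bytes):
                out.update(_maker_note_entries(value))
                continue
            text = _decode(value)
            if text is None:
                continue
            name = ExifTags.TAGS.get(tag_id, f"Tag{tag_id}")
            out.setdefault(name, text)
    return out


def read_exif_datetime(image: str | Path) -> datetime | None:
    """The EXIF ``DateTimeOriginal`` of ``image``, or None if absent."""
    with Image.open(image) as im:
        exif = im.getexif()
        raw = exif.get_ifd(ExifTags.IFD.Exif).get(_DATETIME_ORIGINAL) \
            or exif.get(306)  # fall back to IFD0 DateTime
    if not raw:
        return None
    try:
        return datetime.strptime(str(raw), _EXIF_DATETIME_FORMAT)
    except ValueError:
        logger.warning("unparseable EXIF timestamp %r in %s", raw, image)
        return None


def populate_from_metadata(table: ImageTable, key: str,
                           target: str) -> ImageTable:
    """Fill the Note field ``target`` of every record from metadata ``key``.

    Each record's image is read and its value for ``key`` written into
    ``target``; records whose image lacks the key (or cannot be read) get
    an empty value and a logged warning.  Existing entries in ``target``
    are overwritten, so the operation is idempotent.
    """
    spec = table.schema[target]
    if spec.field_type is not FieldType.NOTE:
        raise ValueError(f"populate target {target!r} must be a Note field")
    out = table.copy()
    for rec in out.records:
        path = Path(out.root) / rec.values["RelativePath"] / rec.values["File"]
        meta = list_metadata(path)
        if key in meta:
            rec.values[target] = meta[key]
        else:
            logger.warning("%s: no metadata key %r", path, key)
            rec.values[target] = ""
    return out
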