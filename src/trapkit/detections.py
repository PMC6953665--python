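"""Import and threshold recognizer output (MegaDetector-style JSON).

A detector run over an image set emits, per file, zero or more candidate
entities, each with a category (animal / person / vehicle), a confidence
in [0, 1] and a normalized bounding box ``(x, y, w, h)`` with origin at
the image's top-left.  This module parses that JSON, filters detections
by a confidence threshold chosen by the analyst, and joins the surviving
files against an :class:`~trapkit.store.ImageTable` to build a selection.

The accepted dialect: ``{"images": [{"file": ..., "detections":
[{"category": ..., "conf": ..., "bbox": [x, y, w, h]}, ...]}, ...]}``
with numeric category codes "1"/"2"/"3" mapping to animal/person/vehicle;
unknown codes are preserved as opaque labels with a warning.  A detection
is kept when its confidence is >= the threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .store import FileSelection, ImageTable

__all__ = ["Detection", "DetectionSet", "load_detections",
           "filter_detections", "select_detected"]

logger = logging.getLogger(__name__)

CATEGORY_CODES = {"1": "animal", "2": "person", "3": "vehicle"}


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class Detection:
    """One candidate entity in one image."""

    category: str
    confidence: float
    bbox: tuple[float, float, float, float]  # (x, y, w, h), normalized

    def __post_init__(self):
        x, y, w, h = self.bbox
        if not 0.0 <= self.confidence <= 1.0:
            raise DetectionError(
                f"confidence {self.confidence} outside [0, 1]")
        if x < 0 or y < 0 or w < 0 or h < 0 or x + w > 1 or y + h > 1:
            raise DetectionError(
                f"bbox {self.bbox} does not lie within the unit square")


@dataclass(frozen=True)
class DetectionSet:
    """Per-file detection lists, keyed by the file path in the JSON."""

    by_file: dict[str, tuple[Detection, ...]]

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_file.values())

    def max_confidence(self, file: str) -> float:
        dets = self.by_file.get(file, ())
        return max((d.confidence for d in dets), default=0.0)


def _parse_detection(obj: dict, where: str) -> Detection:
    if not isinstance(obj, dict):
        raise DetectionError(f"{where}: detection must be an object")
    for key in ("category", "conf", "bbox"):
        if key not in obj:
            raise DetectionError(f"{where}: missing {key!r}")
    code = str(obj["category"])
    category = CATEGORY_CODES.get(code)
    if category is None:
        logger.warning("%s: unknown category code %r kept as-is", where, code)
        category = code
    bbox = obj["bbox"]
    if not isinstance(bbox, (list, tuple)) or len(bbox) != 4:
        raise DetectionError(f"{where}: bbox must have 4 numbers")
    try:
        det = Detection(category, float(obj["conf"]),
                        tuple(float(v) for v in bbox))
    except (TypeError, ValueError) as exc:
        raise DetectionError(f"{where}: {exc}") from exc
    return det


def load_detections(path: str | Path) -> DetectionSet:
    """Parse a detector output file; errors name the offending entry."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DetectionError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("images"), list):
        raise DetectionError(f"{path}: expected an object with 'images' list")
    by_file: dict[str, tuple[Detection, ...]] = {}
    for i, entry in enumerate(doc["images"]):
        where = f"{path}: images[{i}]"
        if not isinstance(entry, dict) or "file" not in entry:
            raise DetectionError(f"{where}: missing 'file'")
        dets = entry.get("detections", [])
        if not isinstance(dets, list):
            raise DetectionError(f"{where}: 'detections' must be a list")
        by_file[str(entry["file"])] = tuple(
            _parse_detection(d, f"{where}.detections[{j}]")
            for j, d in enumerate(dets))
    return DetectionSet(by_file)


def filter_detections(ds: DetectionSet, threshold: float) -> DetectionSet:
    """Keep detections with confidence >= ``threshold``; files are kept
    even when their list empties, so join semantics are unchanged."""
    if not 0.0 <= threshold <= 1.0:
        raise DetectionError(f"threshold {threshold} outside [0, 1]")
    return DetectionSet({
        f: tuple(d for d in dets if d.confidence >= threshold)
        for f, dets in ds.by_file.items()})


def select_detected(table: ImageTable, ds: DetectionSet,
                    threshold: float = 0.0) -> FileSelection:
    """Records whose file has at least one detection above threshold.

    Join key is the ``RelativePath/File`` string (forward slashes); file
    keys in the detection set that match no record are logged, not fatal.
    """
    filtered = filter_detections(ds, threshold)
    by_key: dict[str, int] = {}
    for r in table.records:
        rel = r.values["RelativePath"]
        key = f"{rel}/{r.values['File']}" if rel else r.values["File"]
        by_key[key] = r.record_id
    ids = []
    for f, dets in filtered.by_file.items():
        if not dets:
            continue
        rid = by_key.get(f)
        if rid is None:
            logger.warning("detection file %r matches no record", f)
        else:
            ids.append(rid)
    return FileSelection(ids)
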