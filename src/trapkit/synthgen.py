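"""Deterministic synthetic camera-trap image sets with ground truth.

Real trap-camera data cannot ship with a library, so every end-to-end
test here runs on generated image sets that emulate the features the
rest of the package operates on: timed bursts of frames (motion-trigger
episodes), a static background with a small bright "animal" blob that
moves between frames, greyscale near-black night frames, and injected
EXIF metadata (``DateTimeOriginal`` plus vendor-style tags such as
``Ambient Temperature``, written as text ``key=value`` lines in the
maker note).  A ground-truth table records, per image, its timestamp,
burst index, blob pixels, darkness flag and injected tags, so tests can
compare every recovered quantity against what was actually planted.

Determinism is part of the contract: the same spec and seed produce
byte-identical JPEG files and identical ground truth.

Numerical margins: frames are written as JPEG quality 95; the blob-to-
background luma contrast (default 200 vs ~49) is kept at more than three
times the default differencing threshold of 40, and blob positions
within a burst are at least 8 px apart, so compression noise cannot flip
a mask bit.  Day frames carry a green colour cast (vegetation) so the
greyscale gate of the darkness classifier separates them from night IR
frames even though their luma is low.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from PIL import ExifTags, Image

from .schema import (FieldSpec, FieldType, TemplateSchema, format_datetime,
                     make_schema)

__all__ = ["SyntheticSpec", "ImageTruth", "GroundTruth",
           "generate_image_set", "generate_template_example"]

_DATETIME_ORIGINAL = 36867
_MAKER_NOTE = 37500
_EXIF_DATETIME_FORMAT = "%Y:%m:%d %H:%M:%S"

JPEG_QUALITY = 95
BLOB_SIDE = 5  # blobs are square patches of BLOB_SIDE**2 px by default
_MIN_BLOB_SEPARATION = 8  # px, per axis, within a burst


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a generated image set.

    Defaults model a motion-triggered camera: frames within a burst 10 s
    apart, bursts 600 s apart (so any episode threshold strictly between
    the two recovers the bursts exactly), 96x72 px frames, one 25 px blob
    of luma 200 on a ~49-luma background per daytime frame, and a number
    of trailing night frames that are greyscale and nearly black.
    """

    n_bursts: int = 5
    burst_size_range: tuple[int, int] = (2, 5)
    intra_gap_s: float = 10.0
    inter_gap_s: float = 600.0
    image_size: tuple[int, int] = (96, 72)  # (width, height)
    blob_area_px: int = BLOB_SIDE * BLOB_SIDE
    blob_luma: int = 200
    background_luma: int = 49
    n_dark_frames: int = 3
    start_time: datetime = datetime(2019, 10, 2, 6, 0, 0)
    utc_offset: float = -7.0
    exif_tags: dict = field(default_factory=lambda: {
        "Ambient Temperature": "{temp} C",
        "Moon Phase": "Full",
    })
    seed: int = 0

    def __post_init__(self):
        if self.inter_gap_s <= self.intra_gap_s:
            raise ValueError("inter_gap_s must exceed intra_gap_s")
        if self.blob_luma == self.background_luma:
            raise ValueError("blob_luma must differ from background_luma")
        lo, hi = self.burst_size_range
        if not 1 <= lo <= hi:
            raise ValueError("burst_size_range must satisfy 1 <= min <= max")


@dataclass
class ImageTruth:
    """What was planted in one generated image."""

    file: str
    relative_path: str
    datetime: datetime
    burst_index: int
    blob_count: int
    blob_pixels: list[tuple[int, int]]  # (row, col) of every blob pixel
    is_dark: bool
    tags: dict[str, str]


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    images: list[ImageTruth]

    @property
    def n_bursts(self) -> int:
        return len({im.burst_index for im in self.images})

    def burst_partition(self) -> list[list[str]]:
        """File names grouped by burst, in time order."""
        bursts: dict[int, list[str]] = {}
        for im in self.images:
            bursts.setdefault(im.burst_index, []).append(im.file)
        return [bursts[i] for i in sorted(bursts)]

    def to_json(self) -> dict:
        return {
            "seed": self.spec.seed,
            "images": [{
                "file": im.file,
                "relative_path": im.relative_path,
                "datetime": format_datetime(im.datetime),
                "burst_index": im.burst_index,
                "blob_count": im.blob_count,
                "blob_pixels": [list(p) for p in im.blob_pixels],
                "is_dark": im.is_dark,
                "tags": im.tags,
            } for im in self.images],
        }


def _day_background(spec: SyntheticSpec) -> np.ndarray:
    """Flat colour with the requested luma but a >40 channel spread, so
    daytime frames fail the darkness classifier's greyscale gate."""
    w, h = spec.image_size
    target = spec.background_luma
    g = min(255, target + 21)
    rb = max(0, round((target - 0.587 * g) / 0.413))
    frame = np.empty((h, w, 3), np.uint8)
    frame[:] = (rb, g, rb)
    return frame


def _night_background(spec: SyntheticSpec) -> np.ndarray:
    w, h = spec.image_size
    return np.full((h, w, 3), 12, np.uint8)


def _blob_positions(rng: np.random.Generator, spec: SyntheticSpec,
                    n: int) -> list[tuple[int, int]]:
    """Top-left corners for ``n`` blobs, pairwise >= 8 px apart per axis."""
    w, h = spec.image_size
    side = int(round(spec.blob_area_px ** 0.5))
    positions: list[tuple[int, int]] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 10_000:
            raise ValueError(
                f"cannot place {n} separated blobs in a {w}x{h} frame")
        y = int(rng.integers(0, h - side))
        x = int(rng.integers(0, w - side))
        if all(max(abs(y - py), abs(x - px)) >= _MIN_BLOB_SEPARATION
               for py, px in positions):
            positions.append((y, x))
    return positions


def _paint_blob(frame: np.ndarray, corner: tuple[int, int],
                spec: SyntheticSpec) -> list[tuple[int, int]]:
    side = int(round(spec.blob_area_px ** 0.5))
    y, x = corner
    frame[y:y + side, x:x + side] = spec.blob_luma
    return [(r, c) for r in range(y, y + side) for c in range(x, x + side)]


def _write_jpeg(frame: np.ndarray, path: Path, when: datetime,
                tags: dict[str, str]) -> None:
    exif = Image.Exif()
    stamp = when.strftime(_EXIF_DATETIME_FORMAT)
    exif[306] = stamp  # IFD0 DateTime
    ifd = exif.get_ifd(ExifTags.IFD.Exif)
    ifd[_DATETIME_ORIGINAL] = stamp
    if tags:
        note = "\n".join(f"{k}={v}" for k, v in sorted(tags.items()))
        ifd[_MAKER_NOTE] = note.encode("utf-8")
    Image.fromarray(frame).save(path, quality=JPEG_QUALITY, exif=exif)


def generate_image_set(spec: SyntheticSpec,
                       out: str | Path) -> GroundTruth:
    """Write the image set under ``out`` and return its ground truth.

    Bursts come first, then ``n_dark_frames`` night frames forming one
    final burst of their own (a camera firing on nothing in the dark).
    Files are named ``Img<seq>.jpg`` under ``Station1/``; a
    ``ground_truth.json`` is written beside them.
    """
    out = Path(out)
    folder = out / "Station1"
    folder.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # burst sizes and start times
    lo, hi = spec.burst_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_bursts)]
    if spec.n_dark_frames > 0:
        sizes.append(spec.n_dark_frames)

    truths: list[ImageTruth] = []
    when = spec.start_time
    seq = 0
    for burst_index, size in enumerate(sizes):
        dark_burst = (spec.n_dark_frames > 0
                      and burst_index == len(sizes) - 1)
        positions = ([] if dark_burst
                     else _blob_positions(rng, spec, size))
        if burst_index > 0:
            when = when + timedelta(seconds=spec.inter_gap_s)
        for j in range(size):
            if j > 0:
                when = when + timedelta(seconds=spec.intra_gap_s)
            seq += 1
            name = f"Img{seq:03d}.jpg"
            frame = (_night_background(spec) if dark_burst
                     else _day_background(spec))
            blob_pixels: list[tuple[int, int]] = []
            if not dark_burst:
                blob_pixels = _paint_blob(frame, positions[j], spec)
            tags = {k: v.format(temp=round(5 + 20 * rng.random(), 1),
                                index=seq)
                    for k, v in spec.exif_tags.items()}
            _write_jpeg(frame, folder / name, when, tags)
            truths.append(ImageTruth(
                file=name, relative_path="Station1", datetime=when,
                burst_index=burst_index,
                blob_count=0 if dark_burst else 1,
                blob_pixels=blob_pixels, is_dark=dark_burst, tags=tags))

    gt = GroundTruth(spec, truths)
    (out / "ground_truth.json").write_text(
        json.dumps(gt.to_json(), indent=2) + "\n", encoding="utf-8")
    return gt


def generate_template_example() -> TemplateSchema:
    """The worked example schema of a goat/hiker trail survey.

    Counters for goats and hikers, a Weather choice, free-text notes for
    the analyst's name, comments and station temperature, and flags for
    publicity-worthy shots and deletion candidates.
    """
    user = [
        FieldSpec(FieldType.COUNTER, "GoatCnt", label="Goats",
                  tooltip="A count of how many goats appear in this image.",
                  default_value="0", copyable=True),
        FieldSpec(FieldType.COUNTER, "Hikers", label="Hikers",
                  tooltip="A count of how many hikers appear in this image.",
                  default_value="0", copyable=True),
        FieldSpec(FieldType.CHOICE, "ImageQuality", label="Image Quality",
                  tooltip="System-assessed image quality.",
                  choice_list=("Ok", "Dark"), default_value="Ok"),
        FieldSpec(FieldType.CHOICE, "Weather", label="Weather",
                  tooltip="The weather conditions in this image.",
                  choice_list=("Sunny", "Cloudy", "Foggy"), copyable=True),
        FieldSpec(FieldType.NOTE, "Analyst", label="Analyst",
                  tooltip="Who analyzed this image.", copyable=True),
        FieldSpec(FieldType.NOTE, "Comments", label="Comments",
                  tooltip="Anything noteworthy about this image."),
        FieldSpec(FieldType.NOTE, "Temperature", label="Temperature",
                  tooltip="Ambient temperature recorded by the camera."),
        FieldSpec(FieldType.FLAG, "Publicity", label="Publicity?",
                  tooltip="Is this image good enough to publicize?"),
        FieldSpec(FieldType.FLAG, "Delete", label="Delete?",
                  tooltip="Mark this image for deletion."),
    ]
    return make_schema(user)
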