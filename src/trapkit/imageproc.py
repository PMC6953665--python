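"""Darkness classification and frame differencing.

Small or distant animals are easy to miss in a raw frame.  Because a trap
camera is fixed, the background is nearly static, so comparing a frame
against its temporal neighbours makes anything that appeared, vanished or
moved "pop out": per-pixel brightness differences above a threshold are
rendered white on black.  The combined mode keeps a pixel only when it
differs from *both* the previous and the next frame, which suppresses the
background changes that any single neighbour shares.

Night frames from infrared illumination are greyscale and dark; the
darkness classifier flags them ("Dark" vs "Ok") so analysts can filter
them out in one step.  An image counts as Dark when it is essentially
greyscale (small per-pixel channel spread) and a large fraction of its
pixels fall below a brightness threshold.

Brightness throughout is ITU-R BT.601 luma, ``round(0.299 R + 0.587 G +
0.114 B)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DarknessParams",
    "DiffParams",
    "Darkness",
    "luma",
    "load_pixels",
    "save_mask",
    "classify_darkness",
    "difference_pair",
    "difference_combined",
]


class Darkness(str, Enum):
    DARK = "Dark"
    OK = "Ok"


@dataclass(frozen=True)
class DarknessParams:
    """Thresholds for the Dark/Ok classifier.

    ``pixel_threshold``: luma below which a pixel counts as dark (0-255).
    ``dark_fraction``: minimum fraction of dark pixels for a Dark verdict.
    ``color_tolerance``: maximum max-min channel spread for a pixel to
    count as greyscale; an image is greyscale when >= 90% of sampled
    pixels are.
    ``stride``: sample every ``stride``-th row and column (1 = every
    pixel, exact).
    """

    pixel_threshold: int = 60
    dark_fraction: float = 0.9
    color_tolerance: int = 40
    stride: int = 1

    def __post_init__(self):
        if not 0 <= self.pixel_threshold <= 255:
            raise ValueError("pixel_threshold must be in [0, 255]")
        if not 0.0 <= self.dark_fraction <= 1.0:
            raise ValueError("dark_fraction must be in [0, 1]")
        if not 0 <= self.color_tolerance <= 255:
            raise ValueError("color_tolerance must be in [0, 255]")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class DiffParams:
    """``luma_threshold``: minimum |luma difference| for a white pixel."""

    luma_threshold: int = 40

    def __post_init__(self):
        if not 0 <= self.luma_threshold <= 255:
            raise ValueError("luma_threshold must be in [0, 255]")


_GREYSCALE_IMAGE_FRACTION = 0.9


def _as_grid(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim == 2:  # greyscale -> replicate channels
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[2] < 3 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected an (H, W, 3) pixel grid, got {a.shape}")
    return a[..., :3].astype(np.uint8, copy=False)


def load_pixels(path: str | Path) -> np.ndarray:
    """Decode an image file to an (H, W, 3) uint8 RGB grid."""
    with Image.open(path) as im:
        return _as_grid(np.asarray(im.convert("RGB")))


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as a 1-bit PNG (white = True)."""
    path = Path(path)
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(path)
    return path


def luma(img: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma, rounded to the nearest integer."""
    a = _as_grid(img).astype(np.float64)
    return np.rint(0.299 * a[..., 0] + 0.587 * a[..., 1]
                   + 0.114 * a[..., 2]).astype(np.int16)


def classify_darkness(img: np.ndarray,
                      params: DarknessParams = DarknessParams()) -> Darkness:
    """Classify a frame as Dark or Ok.

    Dark iff the image is greyscale (>= 90% of sampled pixels have channel
    spread <= ``color_tolerance``) AND the fraction of sampled pixels with
    luma < ``pixel_threshold`` is >= ``dark_fraction``.  Colour daytime
    frames are Ok regardless of brightness.
    """
    a = _as_grid(img)[:: params.stride, :: params.stride]
    spread = a.max(axis=-1).astype(np.int16) - a.min(axis=-1)
    greyscale = (spread <= params.color_tolerance).mean() \
        >= _GREYSCALE_IMAGE_FRACTION
    if not greyscale:
        return Darkness.OK
    dark_frac = (luma(a) < params.pixel_threshold).mean()
    return Darkness.DARK if dark_frac >= params.dark_fraction else Darkness.OK


def _check_dims(*grids: np.ndarray) -> None:
    shapes = {g.shape[:2] for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"images must share dimensions, got {shapes}")


def difference_pair(cur: np.ndarray, other: np.ndarray,
                    params: DiffParams = DiffParams()) -> np.ndarray:
    """Boolean mask: True where |luma(cur) - luma(other)| > threshold."""
    cur, other = _as_grid(cur), _as_grid(other)
    _check_dims(cur, other)
    return np.abs(luma(cur) - luma(other)) > params.luma_threshold


def difference_combined(prev: np.ndarray, cur: np.ndarray, next_: np.ndarray,
                        params: DiffParams = DiffParams()) -> np.ndarray:
    """Boolean mask: True only where ``cur`` differs from BOTH neighbours.

    The conjunction removes anything shared with either neighbour, so a
    static background (or an entity present across all three frames)
    comes out black and only the entity unique to the current frame stays
    white.
    """
    prev, cur, next_ = _as_grid(prev), _as_grid(cur), _as_grid(next_)
    _check_dims(prev, cur, next_)
    return difference_pair(cur, prev, params) & difference_pair(
        cur, next_, params)
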