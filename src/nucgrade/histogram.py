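"""Masked-nucleus intensity histograms for AS-OCT images.

The nucleus region of an anterior-segment OCT image is described by a
binary mask (the output of an upstream segmentation step; producing it is
not this package's job). All downstream statistics operate on the
discretized distribution of the pixel intensities inside that mask: a
histogram with a configurable intensity range ``[range_lo, range_hi]`` and
bin width ``interval``. Bins are half-open ``[L_i, L_i + interval)`` except
the last, which is closed at ``range_hi`` so the upper boundary value is
counted exactly once. Bin indices ``i`` are 1-based, increasing left to
right.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "SeverityLabel",
    "HistogramConfig",
    "NucleusImage",
    "IntensityHistogram",
    "extract_masked_pixels",
    "build_histogram",
    "cumulative_proportions",
    "load_image_pair",
    "write_histogram_csv",
    "read_histogram_csv",
]


class SeverityLabel(IntEnum):
    """Three-level nuclear-cataract severity grade with fixed ordinal codes."""

    NORMAL = 1
    MILD = 2
    SEVERE = 3

    @classmethod
    def from_name(cls, name: str) -> "SeverityLabel":
        try:
            return cls[str(name).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown severity label: {name!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class HistogramConfig:
    """Intensity range and bin width of the nucleus histogram.

    Parameters
    ----------
    range_lo, range_hi
        Inclusive intensity bounds. The default 5-150 window removes the
        near-zero background mass and the sparse very bright tail; the
        full 8-bit window 0-255 is the main alternative.
    interval
        Bin width in intensity units.
    normalize_in_range_only
        If True (default), bin proportions are normalized over the pixels
        that fall inside ``[range_lo, range_hi]`` only, so the retained
        mass sums to one. If False, the denominator is the total masked
        pixel count and out-of-range mass is simply missing.
    """

    range_lo: int = 5
    range_hi: int = 150
    interval: int = 5
    normalize_in_range_only: bool = True

    def __post_init__(self) -> None:
        if self.range_lo >= self.range_hi:
            raise ValueError("range_lo must be < range_hi")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.interval > self.range_hi - self.range_lo:
            raise ValueError("interval must not exceed range_hi - range_lo")

    @property
    def n_bins(self) -> int:
        return math.ceil((self.range_hi - self.range_lo) / self.interval)

    @property
    def left_edges(self) -> np.ndarray:
        return self.range_lo + self.interval * np.arange(self.n_bins)

    def to_dict(self) -> dict:
        return {
            "range_lo": self.range_lo,
            "range_hi": self.range_hi,
            "interval": self.interval,
            "normalize_in_range_only": self.normalize_in_range_only,
        }


@dataclass
class NucleusImage:
    """An 8-bit grayscale AS-OCT image with its binary nucleus mask."""

    pixels: np.ndarray
    mask: np.ndarray
    sample_id: str = ""
    label: Optional[SeverityLabel] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D single-channel array")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels {self.pixels.shape} and mask {self.mask.shape} "
                "must have identical dimensions"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must be integer-valued (8-bit grayscale)")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValueError("pixel intensities must lie in [0, 255]; other bit depths are rejected, not converted")


@dataclass
class IntensityHistogram:
    """Discretized, normalized intensity distribution of a masked region.

    ``L[i]`` is the left boundary of bin ``i+1`` (1-based indices in the
    formulas), ``X[i]`` its proportion, ``n_pixels`` the number of in-range
    pixels counted.
    """

    X: np.ndarray
    L: np.ndarray
    interval: int
    n_pixels: int
    config: HistogramConfig = field(default=None)  # type: ignore[assignment]

    @property
    def N(self) -> int:
        return len(self.X)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if len(self.X) != len(self.L):
            raise ValueError("X and L must have equal length")
        if np.any(self.X < 0):
            raise ValueError("proportions must be nonnegative")


def extract_masked_pixels(image: NucleusImage) -> np.ndarray:
    """Return the intensities at mask-positive positions (row-major order)."""
    sel = image.mask != 0
    if not sel.any():
        raise ValueError("empty nucleus mask")
    return image.pixels[sel].ravel()


def build_histogram(pixels: Sequence[int], config: HistogramConfig) -> IntensityHistogram:
    """Bin masked-pixel intensities into the configured histogram.

    Pixels outside ``[range_lo, range_hi]`` are discarded before counting.
    Raises ``ValueError`` if no pixel falls inside the range.
    """
    v = np.asarray(pixels)
    if v.size == 0:
        raise ValueError("empty pixel list")
    n_total = v.size
    in_range = v[(v >= config.range_lo) & (v <= config.range_hi)]
    if in_range.size == 0:
        raise ValueError("empty histogram: no pixel inside "
                         f"[{config.range_lo}, {config.range_hi}]")
    n_bins = config.n_bins
    idx = (in_range.astype(np.int64) - config.range_lo) // config.interval
    # value == range_hi lands in the (closed) last bin
    idx = np.minimum(idx, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    denom = in_range.size if config.normalize_in_range_only else n_total
    return IntensityHistogram(
        X=counts / denom,
        L=config.left_edges.astype(float),
        interval=config.interval,
        n_pixels=int(in_range.size),
        config=config,
    )


def cumulative_proportions(h: IntensityHistogram) -> np.ndarray:
    """Partial sums ``C_i = sum_{j<=i} X_j`` of the bin proportions."""
    return np.cumsum(h.X)


# ---------------------------------------------------------------------------
# I/O

def load_image_pair(image_path, mask_path, sample_id: str = "",
                    label: Optional[SeverityLabel] = None) -> NucleusImage:
    """Load an 8-bit grayscale PNG/TIFF image and its binary mask PNG.

    Images with a bit depth other than 8 or with multiple channels are
    rejected with an error rather than silently converted.
    """
    img = Image.open(image_path)
    if img.mode != "L":
        raise ValueError(
            f"{image_path}: expected 8-bit single-channel image, got mode {img.mode!r}")
    mask_img = Image.open(mask_path)
    if mask_img.mode not in ("L", "1"):
        raise ValueError(f"{mask_path}: mask must be single-channel, got {mask_img.mode!r}")
    pixels = np.asarray(img, dtype=np.uint8)
    mask = (np.asarray(mask_img) != 0).astype(np.uint8)
    return NucleusImage(pixels=pixels, mask=mask, sample_id=sample_id, label=label)


def write_histogram_csv(h: IntensityHistogram, path) -> None:
    """Serialize a histogram to CSV (columns i, L_i, X_i) with a JSON header line."""
    path = Path(path)
    header = json.dumps(h.config.to_dict() if h.config is not None else {})
    lines = [f"# {header}", "i,L_i,X_i"]
    for i, (left, x) in enumerate(zip(h.L, h.X), start=1):
        lines.append(f"{i},{left:g},{float(x)!r}")
    lines.append(f"# n_pixels={h.n_pixels}")
    path.write_text("\n".join(lines) + "\n")


def read_histogram_csv(path) -> IntensityHistogram:
    path = Path(path)
    raw = path.read_text().strip().splitlines()
    cfg = HistogramConfig(**json.loads(raw[0].lstrip("# ")))
    n_pixels = 0
    L, X = [], []
    for line in raw[1:]:
        if line.startswith("#"):
            if "n_pixels=" in line:
                n_pixels = int(line.split("n_pixels=")[1])
            continue
        if line.startswith("i,"):
            continue
        _, left, x = line.split(",")
        L.append(float(left))
        X.append(float(x))
    return IntensityHistogram(X=np.array(X), L=np.array(L),
                              interval=cfg.interval, n_pixels=n_pixels, config=cfg)
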