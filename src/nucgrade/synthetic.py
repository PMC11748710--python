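"""Seeded generator of AS-OCT-like nucleus images for the three severity grades.

Real anterior-segment OCT scans of normal, mild and severe nuclear
cataracts look similar to the eye, but the intensity *histograms* of the
nucleus region differ systematically: a normal lens concentrates its mass
at low intensities while increasing opacity shifts the distribution
upward and grows a bright tail. The generator reproduces exactly that
histogram-level contrast with the simplest mixture that does so:

* a background spike of near-zero pixels (uniform on 0..4),
* an "opacity" component: a normal distribution truncated to [0, 255]
  whose mean/sd grow with severity, rounded to integers,
* a bright tail: uniform on 150..255, with weight growing with severity.

Pixels are placed inside an elliptical nucleus mask; everything outside
the ellipse is zero. No claim of physical OCT realism (no speckle, no
anatomy) — the point is controllable, seeded class separation at the
histogram level. The whole dataset is a pure function of its
configuration: image ``k`` uses derived seed ``seed + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, extract_all
from .histogram import HistogramConfig, NucleusImage, SeverityLabel
from .importance import FeatureTable

__all__ = [
    "ClassProfile",
    "SimConfig",
    "default_profiles",
    "collapsed_profiles",
    "generate_image",
    "generate_dataset",
    "generate_feature_table",
    "pixel_value_pmf",
    "write_dataset",
]

_BACKGROUND_HI = 4     # background spike spans 0..4
_TAIL_LO = 150         # bright tail spans 150..255


@dataclass(frozen=True)
class ClassProfile:
    """Pixel-intensity mixture inside the nucleus for one severity grade."""

    label: SeverityLabel
    mix_weight_background: float
    opacity_mean: float
    opacity_sd: float
    tail_weight: float

    def __post_init__(self) -> None:
        for name in ("mix_weight_background", "tail_weight"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mix_weight_background + self.tail_weight > 1:
            raise ValueError("mixture weights must sum to <= 1")
        if not 0 < self.opacity_mean < 255:
            raise ValueError("opacity_mean must lie inside (0, 255)")
        if self.opacity_sd <= 0:
            raise ValueError("opacity_sd must be positive")

    @property
    def opacity_weight(self) -> float:
        return 1.0 - self.mix_weight_background - self.tail_weight


@dataclass(frozen=True)
class SimConfig:
    """Geometry and cohort size of a simulated dataset."""

    image_size: Tuple[int, int] = (72, 96)          # (height, width)
    nucleus_center: Optional[Tuple[float, float]] = None  # default: image center
    nucleus_axes: Tuple[float, float] = (24.0, 34.0)      # (semi-height, semi-width)
    n_per_class: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        cy, cx = self.center
        ay, ax = self.nucleus_axes
        if ay <= 0 or ax <= 0:
            raise ValueError("degenerate ellipse: axes must be positive")
        if cy - ay < 0 or cy + ay >= h or cx - ax < 0 or cx + ax >= w:
            raise ValueError("ellipse must fit inside the image")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    @property
    def center(self) -> Tuple[float, float]:
        if self.nucleus_center is not None:
            return self.nucleus_center
        h, w = self.image_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


def default_profiles() -> Dict[SeverityLabel, ClassProfile]:
    """Default per-class mixtures: low-concentrated normal, shifted mild,
    strongly shifted severe with a heavier bright tail."""
    return {
        SeverityLabel.NORMAL: ClassProfile(SeverityLabel.NORMAL, 0.30, 30.0, 8.0, 0.00),
        SeverityLabel.MILD: ClassProfile(SeverityLabel.MILD, 0.20, 55.0, 12.0, 0.05),
        SeverityLabel.SEVERE: ClassProfile(SeverityLabel.SEVERE, 0.10, 85.0, 18.0, 0.15),
    }


def collapsed_profiles() -> Dict[SeverityLabel, ClassProfile]:
    """All three classes share one mixture — labels carry no signal."""
    ref = default_profiles()[SeverityLabel.MILD]
    return {
        lab: ClassProfile(lab, ref.mix_weight_background, ref.opacity_mean,
                          ref.opacity_sd, ref.tail_weight)
        for lab in SeverityLabel
    }


def ellipse_mask(shape: Tuple[int, int], center: Tuple[float, float],
                 axes: Tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = center
    ay, ax = axes
    return (((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0).astype(np.uint8)


def _sample_pixels(profile: ClassProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    counts = rng.multinomial(n, [profile.mix_weight_background,
                                 profile.opacity_weight,
                                 profile.tail_weight])
    parts = []
    if counts[0]:
        parts.append(rng.integers(0, _BACKGROUND_HI + 1, size=counts[0]))
    if counts[1]:
        a = (0 - profile.opacity_mean) / profile.opacity_sd
        b = (255 - profile.opacity_mean) / profile.opacity_sd
        vals = stats.truncnorm.rvs(a, b, loc=profile.opacity_mean,
                                   scale=profile.opacity_sd, size=counts[1],
                                   random_state=rng)
        parts.append(np.clip(np.rint(vals), 0, 255).astype(np.int64))
    if counts[2]:
        parts.append(rng.integers(_TAIL_LO, 256, size=counts[2]))
    pixels = np.concatenate(parts).astype(np.uint8)
    rng.shuffle(pixels)
    return pixels


def generate_image(profile: ClassProfile, config: SimConfig, seed: int) -> NucleusImage:
    """One seeded image: mixture pixels inside the ellipse, zeros outside."""
    rng = np.random.default_rng(seed)
    mask = ellipse_mask(config.image_size, config.center, config.nucleus_axes)
    pixels = np.zeros(config.image_size, dtype=np.uint8)
    sel = mask != 0
    pixels[sel] = _sample_pixels(profile, int(sel.sum()), rng)
    return NucleusImage(pixels=pixels, mask=mask,
                        sample_id=f"{profile.label.name.lower()}_{seed}",
                        label=profile.label)


def generate_dataset(
    config: SimConfig,
    profiles: Optional[Dict[SeverityLabel, ClassProfile]] = None,
) -> List[NucleusImage]:
    """``n_per_class`` seeded images per severity grade (derived seeds seed+k)."""
    profiles = profiles or default_profiles()
    images = []
    k = 0
    for label in sorted(profiles, key=int):
        for _ in range(config.n_per_class):
            img = generate_image(profiles[label], config, seed=config.seed + k)
            img.sample_id = f"{label.name.lower()}_{k:05d}"
            images.append(img)
            k += 1
    return images


def generate_feature_table(
    config: SimConfig,
    hist_config: Optional[HistogramConfig] = None,
    profiles: Optional[Dict[SeverityLabel, ClassProfile]] = None,
) -> FeatureTable:
    """Generate images and extract the 27-feature table in one step."""
    hist_config = hist_config or HistogramConfig()
    images = generate_dataset(config, profiles)
    rows = [extract_all(img, hist_config) for img in images]
    return FeatureTable(
        features=pd.DataFrame(rows, columns=list(FEATURE_NAMES)),
        labels=np.array([int(img.label) for img in images]),
        sample_ids=[img.sample_id for img in images],
    )


def pixel_value_pmf(profile: ClassProfile) -> np.ndarray:
    """Exact pmf over pixel values 0..255 under a profile's mixture.

    The opacity component's pmf is the truncated normal integrated over
    each rounding cell [v-0.5, v+0.5] (clipped to the truncation bounds).
    Useful as an analytic oracle for sample-mean and divergence checks.
    """
    pmf = np.zeros(256)
    pmf[: _BACKGROUND_HI + 1] += profile.mix_weight_background / (_BACKGROUND_HI + 1)
    a = (0 - profile.opacity_mean) / profile.opacity_sd
    b = (255 - profile.opacity_mean) / profile.opacity_sd
    v = np.arange(256)
    hi = stats.truncnorm.cdf(np.minimum(v + 0.5, 255), a, b,
                             loc=profile.opacity_mean, scale=profile.opacity_sd)
    lo = stats.truncnorm.cdf(np.maximum(v - 0.5, 0), a, b,
                             loc=profile.opacity_mean, scale=profile.opacity_sd)
    pmf += profile.opacity_weight * (hi - lo)
    pmf[_TAIL_LO:] += profile.tail_weight / (256 - _TAIL_LO)
    return pmf / pmf.sum()


def write_dataset(images: Sequence[NucleusImage], out_dir, seed: int = 0) -> Path:
    """Write PNG image/mask pairs plus a manifest CSV; returns the manifest path."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for k, img in enumerate(images):
        image_name = f"{img.sample_id}.png"
        mask_name = f"{img.sample_id}_mask.png"
        Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(out_dir / image_name)
        Image.fromarray((img.mask * 255).astype(np.uint8), mode="L").save(out_dir / mask_name)
        records.append({
            "sample_id": img.sample_id,
            "label": img.label.name.lower() if img.label is not None else "",
            "image": image_name,
            "mask": mask_name,
            "seed": seed + k,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest
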