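"""The 27-feature visual catalog: 23 histogram statistics + 4 intensity statistics.

The histogram statistics treat the 1-based bin index ``i`` as the
"discretized intensity": moments, deviations, entropy and uniformity are
computed on indices weighted by the bin proportions ``X_i``, while the
percentile/range features (D-Minimum, D-Maximum, D-Interquartile, D-Range,
IHC-Dispersion) are expressed in intensity units via the bin left
boundaries ``L_i``. The four clinical intensity features are computed on
the raw masked pixels with no range filtering.

Degenerate cases follow fixed conventions so feature tables stay finite:
skewness and kurtosis of a single-occupied-bin histogram are 0 (a 0/0
case), and the quartile coefficient of dispersion is 0 when the quartile
boundaries sum to zero. Each such fallback is logged.
"""

from __future__ import annotations

import logging
from typing import Dict, Sequence

import numpy as np

from .histogram import (
    HistogramConfig,
    IntensityHistogram,
    NucleusImage,
    build_histogram,
    cumulative_proportions,
    extract_masked_pixels,
)

logger = logging.getLogger(__name__)

#: Canonical feature order; tables and serialized vectors always use it.
FEATURE_NAMES: tuple = (
    "D-Mean", "D-Variance", "D-Skewness", "D-Kurtosis", "D-Median",
    "IH-Mean", "IHR-Mean", "IH-Median", "IHC-Variation", "D-Entropy",
    "D-Uniformity", "D-Ten", "D-Ninety", "IH-Mode", "D-Minimum",
    "D-Maximum", "D-Interquartile", "D-Range", "IHC-Dispersion",
    "G-Maximum", "GI-Maximum", "G-Minimum", "GI-Minimum",
    "I-Mean", "I-Median", "I-STD", "I-Maximum",
)

HISTOGRAM_FEATURE_NAMES = FEATURE_NAMES[:23]
INTENSITY_FEATURE_NAMES = FEATURE_NAMES[23:]

#: Features whose value is a histogram bin index (a location), as opposed to
#: a raw statistic. Used by the redundancy tie-break in feature selection.
INDEX_VALUED_FEATURES = frozenset(
    {"D-Median", "D-Ten", "D-Ninety", "IH-Mode", "GI-Maximum", "GI-Minimum"}
)

_EPS = 1e-300


def _first_index_reaching(C: np.ndarray, q: float) -> int:
    """Smallest 1-based bin index whose cumulative proportion reaches q·C_N."""
    target = q * C[-1]
    return int(np.searchsorted(C, target - 1e-12)) + 1


def compute_histogram_features(
    h: IntensityHistogram, renormalize_ihr: bool = False
) -> Dict[str, float]:
    """Compute the 23 histogram-based statistical features.

    Parameters
    ----------
    h
        A valid histogram with positive in-range mass.
    renormalize_ihr
        The robust mean absolute deviation (IHR-Mean) sums ``|i-mu| X_i``
        over the bins between the 10th and 90th percentile indices. By
        default the truncated mass is *not* renormalized, matching the
        formula as written; set True to divide by the retained mass.
    """
    if h.n_pixels == 0 or h.X.sum() <= 0:
        raise ValueError("empty histogram")
    X = h.X
    L = h.L
    N = h.N
    i = np.arange(1, N + 1, dtype=float)

    mu = float(np.sum(i * X))
    var = float(np.sum((i - mu) ** 2 * X))
    if var > 1e-24:
        skew = float(np.sum((i - mu) ** 3 * X) / var ** 1.5)
        kurt = float(np.sum((i - mu) ** 4 * X) / var ** 2) - 3.0
    else:
        logger.debug("single-occupied-bin histogram: skewness/kurtosis set to 0")
        skew = 0.0
        kurt = 0.0

    C = cumulative_proportions(h)
    d_median = _first_index_reaching(C, 0.5)
    d_ten = _first_index_reaching(C, 0.10)
    d_ninety = _first_index_reaching(C, 0.90)

    ih_mean = float(np.sum(np.abs(i - mu) * X))
    sel = (i >= d_ten) & (i <= d_ninety)
    ihr = float(np.sum(np.abs(i - mu)[sel] * X[sel]))
    if renormalize_ihr:
        retained = float(X[sel].sum())
        ihr = ihr / retained if retained > 0 else 0.0
    ih_median = float(np.sum(np.abs(i - d_median) * X))
    sigma = float(np.sqrt(var))
    ihc_variation = sigma / mu if mu > 0 else 0.0

    pos = X > 0
    entropy = float(-np.sum(X[pos] * np.log2(X[pos])))
    uniformity = float(np.sum(X ** 2))
    ih_mode = int(np.argmax(X)) + 1  # first maximum on ties

    occ = np.flatnonzero(pos)
    d_minimum = float(L[occ[0]])
    d_maximum = float(L[occ[-1]])
    l25 = float(L[_first_index_reaching(C, 0.25) - 1])
    l75 = float(L[_first_index_reaching(C, 0.75) - 1])
    d_interquartile = l75 - l25
    d_range = d_maximum - d_minimum
    if abs(l75 + l25) > _EPS:
        ihc_dispersion = (l75 - l25) / (l75 + l25)
    else:
        logger.debug("quartile boundaries sum to zero: IHC-Dispersion set to 0")
        ihc_dispersion = 0.0

    if N >= 2:
        g = np.diff(X)  # forward differences over adjacent bins
        g_maximum = float(g.max())
        gi_maximum = int(np.argmax(g)) + 1
        g_minimum = float(g.min())
        gi_minimum = int(np.argmin(g)) + 1
    else:  # no gradient is defined for a single bin
        g_maximum = g_minimum = 0.0
        gi_maximum = gi_minimum = 1

    return {
        "D-Mean": mu,
        "D-Variance": var,
        "D-Skewness": skew,
        "D-Kurtosis": kurt,
        "D-Median": float(d_median),
        "IH-Mean": ih_mean,
        "IHR-Mean": ihr,
        "IH-Median": ih_median,
        "IHC-Variation": ihc_variation,
        "D-Entropy": entropy,
        "D-Uniformity": uniformity,
        "D-Ten": float(d_ten),
        "D-Ninety": float(d_ninety),
        "IH-Mode": float(ih_mode),
        "D-Minimum": d_minimum,
        "D-Maximum": d_maximum,
        "D-Interquartile": d_interquartile,
        "D-Range": d_range,
        "IHC-Dispersion": ihc_dispersion,
        "G-Maximum": g_maximum,
        "GI-Maximum": float(gi_maximum),
        "G-Minimum": g_minimum,
        "GI-Minimum": float(gi_minimum),
    }


def compute_intensity_features(
    pixels: Sequence[int], sample_std: bool = False
) -> Dict[str, float]:
    """The four clinical intensity statistics on all masked pixels.

    I-STD uses the population denominator ``n`` by default
    (``sample_std=True`` switches to ``n - 1``).
    """
    v = np.asarray(pixels, dtype=float)
    if v.size == 0:
        raise ValueError("empty pixel list")
    ddof = 1 if (sample_std and v.size > 1) else 0
    return {
        "I-Mean": float(v.mean()),
        "I-Median": float(np.median(v)),
        "I-STD": float(v.std(ddof=ddof)),
        "I-Maximum": float(v.max()),
    }


def extract_all(
    image: NucleusImage,
    config: HistogramConfig | None = None,
    renormalize_ihr: bool = False,
    sample_std: bool = False,
) -> Dict[str, float]:
    """Extract the full 27-feature vector from an image + mask pair.

    Histogram features are computed on the in-range masked pixels under
    ``config`` (default 5-150, width 5); intensity features on all masked
    pixels. Returns an ordered mapping over :data:`FEATURE_NAMES`.
    """
    config = config or HistogramConfig()
    pixels = extract_masked_pixels(image)
    h = build_histogram(pixels, config)
    values = compute_histogram_features(h, renormalize_ihr=renormalize_ihr)
    values.update(compute_intensity_features(pixels, sample_std=sample_std))
    return {name: values[name] for name in FEATURE_NAMES}
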