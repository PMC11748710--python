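"""End-to-end orchestration: extract -> analyze -> train/evaluate -> ablate.

Thin glue over the library modules so the command-line interface and
scripted runs share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .emrr import EMRRModel, fit_emrr
from .features import FEATURE_NAMES, extract_all
from .histogram import HistogramConfig, NucleusImage
from .importance import FeatureTable, stratified_split
from .metrics import ConfusionSummary, MetricsReport, accuracy, compute_metrics, confusion

logger = logging.getLogger(__name__)

#: The four histogram ablation settings: full/windowed range x coarse/fine bins.
ABLATION_SETTINGS: Tuple[HistogramConfig, ...] = (
    HistogramConfig(0, 255, 10),
    HistogramConfig(0, 255, 5),
    HistogramConfig(5, 150, 10),
    HistogramConfig(5, 150, 5),
)


def extract_table(images: Sequence[NucleusImage],
                  config: Optional[HistogramConfig] = None) -> FeatureTable:
    """Feature table from a batch of images (rows in input order)."""
    config = config or HistogramConfig()
    rows, labels, ids = [], [], []
    for img in images:
        rows.append(extract_all(img, config))
        labels.append(int(img.label) if img.label is not None else 0)
        ids.append(img.sample_id)
    return FeatureTable(features=pd.DataFrame(rows, columns=list(FEATURE_NAMES)),
                        labels=np.array(labels), sample_ids=ids)


def grouped_split(groups: Sequence, test_fraction: float, seed: int
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Participant-level split: whole groups go to one side or the other."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    n_test = min(max(int(round(test_fraction * len(uniq))), 1), len(uniq) - 1)
    test_groups = set(uniq[:n_test].tolist())
    mask = np.array([g in test_groups for g in groups])
    return np.flatnonzero(~mask), np.flatnonzero(mask)


@dataclass
class EvalResult:
    model: EMRRModel
    metrics: MetricsReport
    confusion: ConfusionSummary
    accuracy: float
    train_idx: np.ndarray
    test_idx: np.ndarray


def train_eval(
    table: FeatureTable,
    selected: Optional[Sequence[str]] = None,
    lam: float = 1.0,
    standardize: bool = True,
    split_seed: int = 0,
    test_fraction: float = 0.3,
    groups: Optional[Sequence] = None,
    split: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> EvalResult:
    """Fit the classifier on a train split and score it on the held-out rows.

    The split is stratified by severity label unless ``groups`` (a
    per-sample participant id) is given, in which case whole participants
    are assigned to one side; an explicit ``split`` overrides both.
    """
    if selected is not None:
        table = table.select(selected)
    if split is not None:
        train_idx, test_idx = split
    elif groups is not None:
        train_idx, test_idx = grouped_split(groups, test_fraction, split_seed)
    else:
        train_idx, test_idx = stratified_split(table.labels, test_fraction, split_seed)
    train = table.subset(train_idx)
    test = table.subset(test_idx)
    model = fit_emrr(train.features, train.labels, lam=lam, standardize=standardize)
    pred = model.predict(test.features)
    classes = list(model.classes)
    lut = {int(c): c for c in classes}
    cm = confusion([lut[int(v)] for v in test.labels], [lut[int(v)] for v in pred],
                   classes=classes)
    return EvalResult(model=model, metrics=compute_metrics(cm), confusion=cm,
                      accuracy=accuracy(test.labels, pred),
                      train_idx=train_idx, test_idx=test_idx)


def ablate(
    images: Sequence[NucleusImage],
    lam: float = 1.0,
    standardize: bool = True,
    split_seed: int = 0,
    test_fraction: float = 0.3,
    settings: Sequence[HistogramConfig] = ABLATION_SETTINGS,
) -> pd.DataFrame:
    """Re-extract and re-evaluate under each histogram setting on one shared split.

    Returns one row per (range, interval) setting with the held-out macro
    metrics and plain accuracy.
    """
    labels = [int(img.label) for img in images]
    split = stratified_split(labels, test_fraction, split_seed)
    rows = []
    for cfg in settings:
        table = extract_table(images, cfg)
        res = train_eval(table, lam=lam, standardize=standardize, split=split)
        row = {
            "range": f"{cfg.range_lo}-{cfg.range_hi}",
            "interval": cfg.interval,
            "accuracy": res.accuracy,
        }
        row.update({f"macro_{k}": res.metrics.macro[k] for k in res.metrics.macro.index})
        rows.append(row)
    return pd.DataFrame(rows)
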