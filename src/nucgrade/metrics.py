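"""Confusion-matrix accounting and the five evaluation measures.

Each class is scored one-vs-rest from its TP/FN/FP/TN counts:

    ACC = (TP+TN)/(TP+FP+TN+FN)   PRE = TP/(TP+FP)   SEN = TP/(TP+FN)
    SPE = TN/(TN+FP)              F1  = 2*PRE*SEN/(PRE+SEN)

The headline multi-class figures are macro averages (unweighted mean over
classes); the pooled micro accuracy (trace of the count matrix over the
total) is reported alongside, since for a three-level task the macro
one-vs-rest accuracy and the plain fraction-correct differ. Cells with a
zero denominator are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionSummary", "confusion", "compute_metrics", "MetricsReport"]

METRIC_NAMES = ("ACC", "PRE", "SEN", "SPE", "F1")


@dataclass
class ConfusionSummary:
    """C x C count matrix (rows = truth, columns = prediction) plus one-vs-rest counts."""

    matrix: np.ndarray
    classes: List

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("count matrix must be square")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def per_class_counts(self) -> pd.DataFrame:
        """One-vs-rest TP, FN, FP, TN per class."""
        m = self.matrix
        tp = np.diag(m)
        fn = m.sum(axis=1) - tp
        fp = m.sum(axis=0) - tp
        tn = m.sum() - tp - fn - fp
        return pd.DataFrame(
            {"TP": tp, "FN": fn, "FP": fp, "TN": tn},
            index=[str(c) for c in self.classes],
        )

    def to_csv(self, path) -> None:
        names = [str(c) for c in self.classes]
        pd.DataFrame(self.matrix, index=names, columns=names).to_csv(
            path, index_label="truth\\pred")


def confusion(truth: Sequence, predicted: Sequence, classes=None) -> ConfusionSummary:
    """Tally a count matrix from paired truth/prediction label lists."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted) or len(truth) == 0:
        raise ValueError("truth and predicted must have equal nonzero length")
    if classes is None:
        classes = sorted(set(truth) | set(predicted))
    classes = list(classes)
    lut = {c: k for k, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in lut or p not in lut:
            raise ValueError(f"unknown label: {t if t not in lut else p!r}")
        m[lut[t], lut[p]] += 1
    return ConfusionSummary(matrix=m, classes=classes)


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    """The five measures for one one-vs-rest cell; 0 with a flag on 0/0."""
    out = {}
    flags = []

    def safe(name, num, den):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    out["ACC"] = safe("ACC", tp + tn, tp + fp + tn + fn)
    out["PRE"] = safe("PRE", tp, tp + fp)
    out["SEN"] = safe("SEN", tp, tp + fn)
    out["SPE"] = safe("SPE", tn, tn + fp)
    out["F1"] = safe("F1", 2 * out["PRE"] * out["SEN"], out["PRE"] + out["SEN"])
    out["zero_denominator"] = flags
    return out


@dataclass
class MetricsReport:
    per_class: pd.DataFrame  # one row per class, columns ACC..F1
    macro: pd.Series
    micro_accuracy: float
    flags: dict

    def to_csv(self, path) -> None:
        table = self.per_class.copy()
        table.loc["macro"] = self.macro
        table.loc["micro", "ACC"] = self.micro_accuracy
        table.to_csv(path, index_label="class")


def compute_metrics(cm: ConfusionSummary) -> MetricsReport:
    """Per-class and macro-averaged measures from a confusion summary."""
    counts = cm.per_class_counts()
    rows = {}
    flags = {}
    for cls, row in counts.iterrows():
        m = binary_metrics(row["TP"], row["FN"], row["FP"], row["TN"])
        flags[cls] = m.pop("zero_denominator")
        rows[cls] = m
    per_class = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    macro = per_class.mean(axis=0)
    micro = float(np.trace(cm.matrix)) / cm.total
    return MetricsReport(per_class=per_class, macro=macro,
                         micro_accuracy=micro, flags=flags)


def accuracy(truth: Sequence, predicted: Sequence) -> float:
    """Plain fraction of correct predictions (micro accuracy)."""
    t = np.asarray([int(v) for v in truth])
    p = np.asarray([int(v) for v in predicted])
    if t.shape != p.shape or t.size == 0:
        raise ValueError("truth and predicted must have equal nonzero length")
    return float(np.mean(t == p))
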