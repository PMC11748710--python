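"""Feature-importance explanation and selection: retraining Shapley + PCC.

The importance of a feature is its Shapley value under full model
retraining: for feature ``i`` and feature set ``T``,

    phi_i = sum over S subset of T\\{i} of
            |S|! (|T|-|S|-1)! / |T|!  *  [ f_{S+i}(y_{S+i}) - f_S(y_S) ]

where ``f_S`` is the classifier retrained on feature subset ``S`` and its
output is the predicted class probability. The empty-subset model predicts
the training-label class frequencies. Exact enumeration retrains ``2^|T|``
models and is capped at 12 features; beyond that a permutation-sampling
estimator (an unbiased Monte-Carlo version of the same sum, with
antithetic permutation pairs for variance reduction) is used.

Pearson correlation supplies the complementary redundancy view: a
feature-by-feature correlation matrix plus each feature's correlation with
the ordinal severity code. Selection drops features whose overall Shapley
magnitude is below a floor, then resolves redundant pairs (high |PCC| or
explicitly listed) by keeping the higher-Shapley member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from math import factorial
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .emrr import fit_emrr
from .features import FEATURE_NAMES, INDEX_VALUED_FEATURES
from .histogram import SeverityLabel
from .metrics import accuracy

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "SelectionRule",
    "ImportanceReport",
    "pcc",
    "pcc_matrix",
    "shap_values",
    "overall_shap",
    "per_class_shap",
    "single_feature_accuracy",
    "select_features",
    "compute_importance_report",
    "load_clinical_importance",
    "clinical_selection_rule",
    "stratified_split",
]

_EXACT_CAP = 12


# ---------------------------------------------------------------------------
# Feature table container

@dataclass
class FeatureTable:
    """A cohort's feature vectors with severity labels."""

    features: pd.DataFrame            # columns = feature names, numeric
    labels: np.ndarray                # ordinal severity codes
    sample_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray([int(v) for v in self.labels])
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features must have equal length")
        if not self.sample_ids:
            self.sample_ids = [f"s{k}" for k in range(len(self.features))]

    @property
    def feature_names(self) -> List[str]:
        return list(self.features.columns)

    @property
    def n_samples(self) -> int:
        return len(self.features)

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[k] for k in idx],
        )

    def select(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.features[list(names)], self.labels,
                            list(self.sample_ids))

    def to_csv(self, path) -> None:
        df = self.features.copy()
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = [SeverityLabel(v).name.lower() for v in self.labels]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       id_col: str = "sample_id") -> "FeatureTable":
        labels = [
            int(v) if str(v).isdigit() else int(SeverityLabel.from_name(v))
            for v in df[label_col]
        ]
        ids = [str(v) for v in df[id_col]] if id_col in df.columns else []
        feats = df.drop(columns=[c for c in (label_col, id_col) if c in df.columns])
        return cls(features=feats.astype(float), labels=np.asarray(labels),
                   sample_ids=ids)


def stratified_split(labels: Sequence, test_fraction: float, seed: int
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled train/test index split (every class in both halves)."""
    labels = np.asarray([int(v) for v in labels])
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


# ---------------------------------------------------------------------------
# Pearson correlation

def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; 0 (flagged in the log) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sx = n * np.sum(x * x) - np.sum(x) ** 2
    sy = n * np.sum(y * y) - np.sum(y) ** 2
    if sx <= 0 or sy <= 0:
        logger.debug("constant input to pcc: returning 0")
        return 0.0
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    return float(np.clip(num / np.sqrt(sx * sy), -1.0, 1.0))


def pcc_matrix(table: FeatureTable) -> pd.DataFrame:
    """Symmetric feature-by-feature correlation matrix.

    The diagonal is 1 for non-constant features and 0 for constant ones
    (a constant feature correlates with nothing, including itself here).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    names = table.feature_names
    X = table.features.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    M = np.zeros((len(names), len(names)))
    for a in range(len(names)):
        if not const[a]:
            M[a, a] = 1.0
        for b in range(a + 1, len(names)):
            r = pcc(X[:, a], X[:, b])
            M[a, b] = M[b, a] = r
    return pd.DataFrame(M, index=names, columns=names)


# ---------------------------------------------------------------------------
# Retraining Shapley values

class _FrequencyModel:
    """Empty-subset baseline: predicts the training-label class frequencies."""

    def __init__(self, y: np.ndarray, classes: Sequence[int]):
        y = np.asarray(y)
        self.freq = np.array([np.mean(y == c) for c in classes])

    def predict_proba(self, X) -> np.ndarray:
        n = np.asarray(X).shape[0]
        return np.tile(self.freq, (n, 1))


def default_model_factory(lam: float = 1.0, standardize: bool = True
                          ) -> Callable:
    """Factory of factories: EMRR retrained per feature subset.

    The returned callable maps ``(X, y)`` to a fitted predictor with a
    ``predict_proba`` method; a zero-column ``X`` yields the class-frequency
    baseline.
    """
    def factory(X: np.ndarray, y: np.ndarray):
        classes = sorted(set(int(v) for v in y))
        if X.shape[1] == 0:
            return _FrequencyModel(y, classes)
        return fit_emrr(X, y, lam=lam, standardize=standardize, classes=classes)
    return factory


class _SubsetPredictions:
    """Memoized per-subset retrain-and-predict, keyed by feature frozenset."""

    def __init__(self, X: np.ndarray, y: np.ndarray, factory: Callable,
                 max_bytes: int = 200_000_000):
        self.X = X
        self.y = y
        self.factory = factory
        self.cache: Dict[frozenset, np.ndarray] = {}
        self.entry_bytes = None
        self.max_bytes = max_bytes
        self.fits = 0

    def __call__(self, subset: frozenset) -> np.ndarray:
        hit = self.cache.get(subset)
        if hit is not None:
            return hit
        cols = sorted(subset)
        Xs = self.X[:, cols]
        model = self.factory(Xs, self.y)
        proba = np.asarray(model.predict_proba(Xs), dtype=float)
        if proba.ndim == 1:
            proba = proba[:, None]
        self.fits += 1
        if self.entry_bytes is None:
            self.entry_bytes = proba.nbytes
        if len(self.cache) * (self.entry_bytes or 1) < self.max_bytes:
            self.cache[subset] = proba
        return proba


def shap_values(
    table: FeatureTable,
    model_factory: Optional[Callable] = None,
    mode: str = "exact",
    n_permutations: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample, per-feature, per-class retraining Shapley values.

    Returns an array of shape ``(n_samples, n_features, n_classes)`` where
    entry ``[s, i, c]`` is feature ``i``'s Shapley contribution to the
    model's predicted probability of class ``c`` for sample ``s``. Exact
    mode enumerates every feature subset (capped at 12 features); sampled
    mode averages marginal contributions over ``n_permutations`` random
    feature orderings drawn as antithetic (permutation, reverse) pairs.
    """
    factory = model_factory or default_model_factory()
    names = table.feature_names
    T = len(names)
    y = table.labels
    X = table.features.to_numpy(dtype=float)
    predict = _SubsetPredictions(X, y, factory)
    base = predict(frozenset())
    n, C = base.shape
    phi = np.zeros((n, T, C))

    if mode == "exact":
        if T > _EXACT_CAP:
            raise ValueError(
                f"exact Shapley infeasible for {T} features (> {_EXACT_CAP}), use sampled")
        fT = factorial(T)
        for i in range(T):
            rest = [j for j in range(T) if j != i]
            for r in range(T):
                w = factorial(r) * factorial(T - r - 1) / fT
                for S in combinations(rest, r):
                    S = frozenset(S)
                    phi[:, i, :] += w * (predict(S | {i}) - predict(S))
        return phi

    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    perms = []
    while len(perms) < n_permutations:
        p = rng.permutation(T)
        perms.append(p)
        if len(perms) < n_permutations:
            perms.append(p[::-1])  # antithetic partner
    for p in perms:
        S = frozenset()
        prev = predict(S)
        for j in p:
            S = S | {j}
            cur = predict(S)
            phi[:, j, :] += cur - prev
            prev = cur
    phi /= len(perms)
    return phi


def overall_shap(phi: np.ndarray, feature_names: Sequence[str]) -> pd.Series:
    """Mean absolute Shapley value over samples and classes, per feature."""
    return pd.Series(np.abs(phi).mean(axis=(0, 2)), index=list(feature_names))


def per_class_shap(phi: np.ndarray, feature_names: Sequence[str],
                   classes: Sequence) -> pd.DataFrame:
    """Mean absolute Shapley value per (feature, class)."""
    return pd.DataFrame(np.abs(phi).mean(axis=0), index=list(feature_names),
                        columns=[str(SeverityLabel(int(c))) if int(c) in (1, 2, 3)
                                 else str(c) for c in classes])


# ---------------------------------------------------------------------------
# Per-feature recognition accuracy

def single_feature_accuracy(
    table: FeatureTable,
    feature: str,
    split_seed: int = 0,
    test_fraction: float = 0.3,
    lam: float = 1.0,
    standardize: bool = True,
) -> float:
    """Held-out accuracy of the classifier trained on one feature alone.

    A constant feature degenerates to an intercept-only fit whose accuracy
    is the majority-class rate of the test split.
    """
    train_idx, test_idx = stratified_split(table.labels, test_fraction, split_seed)
    train = table.subset(train_idx)
    test = table.subset(test_idx)
    model = fit_emrr(train.features[[feature]], train.labels, lam=lam,
                     standardize=standardize)
    pred = model.predict(test.features[[feature]])
    return accuracy(test.labels, pred)


# ---------------------------------------------------------------------------
# Selection

@dataclass(frozen=True)
class SelectionRule:
    """Shapley floor + pairwise-redundancy resolution."""

    shap_floor: float = 0.015
    redundancy_threshold: float = 0.9
    resolved_pairs: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.shap_floor < 0:
            raise ValueError("shap_floor must be >= 0")
        if not 0 < self.redundancy_threshold <= 1:
            raise ValueError("redundancy_threshold must be in (0, 1]")


@dataclass
class ImportanceReport:
    """Per-feature importance summary plus the feature correlation matrix."""

    table: pd.DataFrame                 # index = feature names
    pcc_matrix: Optional[pd.DataFrame] = None
    per_class: Optional[pd.DataFrame] = None

    @property
    def feature_names(self) -> List[str]:
        return list(self.table.index)

    @property
    def overall_shap(self) -> pd.Series:
        return self.table["overall_shap"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")

    def matrix_to_csv(self, path) -> None:
        if self.pcc_matrix is None:
            raise ValueError("report has no PCC matrix")
        self.pcc_matrix.to_csv(path, index_label="feature")


def select_features(report: ImportanceReport, rule: SelectionRule) -> List[str]:
    """Apply the floor-then-redundancy rule; canonical order preserved.

    Redundant pairs come from ``rule.resolved_pairs`` plus any pair whose
    |PCC| reaches ``rule.redundancy_threshold`` (when the report carries a
    matrix). The lower-Shapley member of a pair is dropped; on an exact tie
    the non-index-valued member goes (the raw-statistic partner of a
    location feature), or failing that the alphabetically later name.
    """
    shap = report.overall_shap
    retained = [f for f in report.feature_names if shap[f] >= rule.shap_floor]

    pairs: List[Tuple[str, str]] = [tuple(p) for p in rule.resolved_pairs]
    if report.pcc_matrix is not None:
        M = report.pcc_matrix
        names = list(M.index)
        for a, b in combinations(names, 2):
            if abs(M.loc[a, b]) >= rule.redundancy_threshold and (a, b) not in pairs \
                    and (b, a) not in pairs:
                pairs.append((a, b))

    dropped = set(f for f in report.feature_names if f not in retained)
    for a, b in pairs:
        if a in dropped or b in dropped or a not in shap.index or b not in shap.index:
            continue
        if shap[a] < shap[b]:
            loser = a
        elif shap[b] < shap[a]:
            loser = b
        else:  # exact tie
            a_idx, b_idx = a in INDEX_VALUED_FEATURES, b in INDEX_VALUED_FEATURES
            if a_idx != b_idx:
                loser = a if not a_idx else b
            else:
                loser = max(a, b)
        dropped.add(loser)
    selected = [f for f in report.feature_names if f not in dropped]
    if not selected:
        raise ValueError("empty selection")
    return selected


# ---------------------------------------------------------------------------
# Orchestration + reference values

def compute_importance_report(
    table: FeatureTable,
    mode: str = "sampled",
    n_permutations: int = 200,
    seed: int = 0,
    split_seed: int = 0,
    test_fraction: float = 0.3,
    lam: float = 1.0,
    standardize: bool = True,
) -> ImportanceReport:
    """Full importance analysis: Shapley, PCC-vs-label, matrix, per-feature accuracy."""
    factory = default_model_factory(lam=lam, standardize=standardize)
    phi = shap_values(table, model_factory=factory, mode=mode,
                      n_permutations=n_permutations, seed=seed)
    names = table.feature_names
    classes = sorted(set(table.labels.tolist()))
    overall = overall_shap(phi, names)
    per_cls = per_class_shap(phi, names, classes)
    y = table.labels.astype(float)
    rows = pd.DataFrame({
        "overall_shap": overall,
        "pcc_label": [pcc(table.features[f].to_numpy(), y) for f in names],
        "single_feature_acc": [
            single_feature_accuracy(table, f, split_seed=split_seed,
                                    test_fraction=test_fraction, lam=lam,
                                    standardize=standardize)
            for f in names
        ],
    })
    for col in per_cls.columns:
        rows[f"shap_{col}"] = per_cls[col]
    return ImportanceReport(table=rows, pcc_matrix=pcc_matrix(table),
                            per_class=per_cls)


def load_clinical_importance() -> ImportanceReport:
    """Importance values reported for the 27-feature catalog on a clinical
    AS-OCT nuclear-cataract cohort, shipped as package data.

    ``single_feature_acc`` is on the [0, 1] scale; the source accuracies
    were percentages. No correlation matrix is available for the cohort.
    """
    with resources.files("nucgrade").joinpath("data/clinical_importance.csv").open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index("feature")
    table = pd.DataFrame({
        "overall_shap": df["overall_shap"],
        "pcc_label": df["pcc_label"],
        "single_feature_acc": df["accuracy_pct"] / 100.0,
    })
    table = table.loc[list(FEATURE_NAMES)]
    return ImportanceReport(table=table, pcc_matrix=None)


def clinical_selection_rule() -> SelectionRule:
    """The documented rule that reproduces the clinical 22-feature subset.

    The three resolved pairs are the gradient statistics against their
    location partners and the discretized median against the raw intensity
    median, whose high mutual correlation makes one member of each pair
    redundant.
    """
    return SelectionRule(
        shap_floor=0.015,
        redundancy_threshold=0.9,
        resolved_pairs=(
            ("G-Maximum", "GI-Maximum"),
            ("G-Minimum", "GI-Minimum"),
            ("D-Median", "I-Median"),
        ),
    )
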