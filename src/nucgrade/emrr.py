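"""Ensemble multi-class ridge regression (EMRR).

One L2-regularized linear regression per severity class, trained
one-vs-all on 0/1 targets, combined by a softmax over the per-class linear
scores and decided by argmax. Each class model has the closed-form
solution

    w_hat = (X^T X + lambda I)^{-1} X^T Y

on the intercept-augmented design matrix (last column all ones). The
penalty is applied to the *full* weight vector including the intercept,
which is the literal form of the training objective here; pass
``penalize_intercept=False`` for the conventional variant that leaves the
intercept free.

Features are z-scored by default using training statistics stored in the
model: ridge shrinkage is scale-sensitive and the 27 visual features span
disparate units (bin indices, proportions, raw intensities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .histogram import SeverityLabel

__all__ = ["EMRRModel", "fit_rr", "fit_emrr"]

_FORMAT_VERSION = 1


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def fit_rr(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    penalize_intercept: bool = True,
) -> np.ndarray:
    """Closed-form ridge solution on an already intercept-augmented design.

    Solves ``(X^T X + lambda I) w = X^T Y`` with a symmetric linear solve.
    ``lam = 0`` requires an invertible Gram matrix and raises otherwise.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    G = X.T @ X
    P = np.eye(G.shape[0])
    if not penalize_intercept:
        P[-1, -1] = 0.0
    A = G + lam * P
    b = X.T @ Y
    try:
        if lam > 0 and penalize_intercept:
            w = scipy.linalg.solve(A, b, assume_a="pos")
        else:
            w = scipy.linalg.solve(A, b, assume_a="sym")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise np.linalg.LinAlgError(
            "singular design, set lambda > 0") from exc
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("singular design, set lambda > 0")
    return w


@dataclass
class EMRRModel:
    """Per-class ridge weight vectors plus the shared penalty and scaling."""

    classes: List[SeverityLabel]
    feature_names: List[str]
    weights: np.ndarray  # shape (C, M+1); intercept last
    lam: float
    standardization: Optional[tuple] = None  # (mean, scale) arrays, or None
    penalize_intercept: bool = True

    # -- prediction -------------------------------------------------------

    def _design(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature(s): {', '.join(missing)}")
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        if self.standardization is not None:
            mean, scale = self.standardization
            X = (X - mean) / scale
        return _augment(X)

    def predict_scores(self, X) -> np.ndarray:
        """Linear scores ``y_c(x) = w_c . x + w_0`` per class, shape (n, C)."""
        return self._design(X) @ self.weights.T

    def predict_proba(self, X) -> np.ndarray:
        """Softmax over the per-class scores (max-subtracted for stability)."""
        s = self.predict_scores(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Class with maximal probability; ties go to the lowest class code."""
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)  # first maximum = lowest code
        return np.array([self.classes[k] for k in idx])

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "classes": [int(c) for c in self.classes],
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "lambda": self.lam,
            "penalize_intercept": self.penalize_intercept,
            "standardization": None
            if self.standardization is None
            else {"mean": self.standardization[0].tolist(),
                  "scale": self.standardization[1].tolist()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "EMRRModel":
        payload = json.loads(Path(path).read_text())
        std = payload["standardization"]
        return cls(
            classes=[SeverityLabel(c) for c in payload["classes"]],
            feature_names=payload["feature_names"],
            weights=np.asarray(payload["weights"], dtype=float),
            lam=payload["lambda"],
            penalize_intercept=payload.get("penalize_intercept", True),
            standardization=None if std is None else (
                np.asarray(std["mean"]), np.asarray(std["scale"])),
        )


def fit_emrr(
    X,
    y: Sequence,
    lam: float = 1.0,
    standardize: bool = True,
    penalize_intercept: bool = True,
    classes: Optional[Sequence] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> EMRRModel:
    """Fit one ridge model per class on one-vs-all 0/1 targets.

    ``X`` may be a DataFrame (column names become the model's feature
    names), an array, or a :class:`~nucgrade.importance.FeatureTable`-like
    object exposing ``features`` and ``labels``. Every class in ``classes``
    (default: the distinct labels seen) must have at least one training
    sample.
    """
    if hasattr(X, "features") and hasattr(X, "labels"):
        y = X.labels
        X = X.features
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is None:
            feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
    y = np.asarray([int(v) for v in y])
    if classes is None:
        classes = sorted(set(y.tolist()))
    classes = [SeverityLabel(c) if c in (1, 2, 3) else c for c in classes]
    present = set(y.tolist())
    absent = [c for c in classes if int(c) not in present]
    if absent:
        raise ValueError(
            "class(es) absent from training data: "
            + ", ".join(str(c) for c in absent))

    standardization = None
    if standardize and X.shape[1] > 0:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)  # constant column guard
        X = (X - mean) / scale
        standardization = (mean, scale)

    Xa = _augment(X)
    weights = np.vstack([
        fit_rr(Xa, (y == int(c)).astype(float), lam,
               penalize_intercept=penalize_intercept)
        for c in classes
    ])
    return EMRRModel(
        classes=list(classes),
        feature_names=list(feature_names),
        weights=weights,
        lam=lam,
        standardization=standardization,
        penalize_intercept=penalize_intercept,
    )
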