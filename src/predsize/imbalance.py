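"""Class-imbalance handling: resampling, cost weighting, recalibration.

All strategies operate on development data only — the validation set is
never touched, which is the leakage guard these tools rely on.  The
default strategy in the simulation experiments is ``none``: no strategy
consistently improves every performance measure, so they are exposed as
opt-in configuration rather than defaults.

Composition rule: at most one resampling step (undersample / oversample /
cost weighting) plus at most one recalibration step (Platt / isotonic);
recalibration needs a held-out calibration split (20% stratified by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.isotonic import IsotonicRegression

from .model_zoo import _fit_logistic

__all__ = [
    "RESAMPLING_STRATEGIES",
    "RECALIBRATION_STRATEGIES",
    "undersample",
    "oversample",
    "cost_weights",
    "Recalibrator",
    "platt_recalibrate",
    "isotonic_recalibrate",
    "calibration_split",
    "knn_minority_interpolation",
]

RESAMPLING_STRATEGIES = ("none", "undersample", "oversample", "class_weight")
RECALIBRATION_STRATEGIES = ("none", "platt", "isotonic")

_CLAMP = 1e-6


def _classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    minority_label = 1 if np.sum(y == 1) <= np.sum(y == 0) else 0
    return np.flatnonzero(y == minority_label), np.flatnonzero(y != minority_label)


def undersample(X: pd.DataFrame, y: np.ndarray, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Randomly remove majority-class rows until the classes are equal."""
    y = np.asarray(y)
    minority, majority = _classes(y)
    if minority.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=minority.size, replace=False)
    idx = np.concatenate([minority, kept_majority])
    rng.shuffle(idx)
    return X.iloc[idx].reset_index(drop=True), y[idx]


def oversample(X: pd.DataFrame, y: np.ndarray, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Resample the minority class with replacement up to the majority size."""
    y = np.asarray(y)
    minority, majority = _classes(y)
    if minority.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    extra = rng.choice(minority, size=majority.size - minority.size, replace=True)
    idx = np.concatenate([minority, extra, majority])
    rng.shuffle(idx)
    return X.iloc[idx].reset_index(drop=True), y[idx]


def cost_weights(y: np.ndarray, ratio: float = 1.0) -> np.ndarray:
    """Per-subject weights giving the minority class ``ratio`` times the majority weight.

    ``ratio = 1`` returns unit weights, reproducing the unweighted fit
    exactly.  Typical illustrative ratios are 10, 20, 100.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    y = np.asarray(y)
    minority, _ = _classes(y)
    w = np.ones(y.size, dtype=float)
    w[minority] = ratio
    return w


@dataclass(frozen=True)
class Recalibrator:
    """A probability-to-probability recalibration map."""

    name: str
    apply: Callable[[np.ndarray], np.ndarray]

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return np.clip(self.apply(np.asarray(p, dtype=float)), 0.0, 1.0)


def platt_recalibrate(p_cal: np.ndarray, y_cal: np.ndarray) -> Recalibrator:
    """Logistic recalibration: p → expit(a + b·logit(p)), (a, b) by ML.

    On the calibration data itself the mapped probabilities have
    calibration slope ≈ 1 and calibration-in-the-large ≈ 0, by the score
    equations of the logistic fit.
    """
    p_cal = np.asarray(p_cal, dtype=float)
    y_cal = np.asarray(y_cal)
    if len(np.unique(y_cal)) < 2:
        warnings.warn("degenerate calibration split: returning identity map", UserWarning)
        return Recalibrator("identity", lambda p: p)
    lo = logit(np.clip(p_cal, _CLAMP, 1.0 - _CLAMP))[:, None]
    if np.ptp(lo) < 1e-12:
        warnings.warn("constant predictions: returning identity map", UserWarning)
        return Recalibrator("identity", lambda p: p)
    est = _fit_logistic(lo, y_cal)
    a = float(est.intercept_[0])
    b = float(est.coef_[0][0])

    def apply(p: np.ndarray) -> np.ndarray:
        return expit(a + b * logit(np.clip(p, _CLAMP, 1.0 - _CLAMP)))

    return Recalibrator("platt", apply)


def isotonic_recalibrate(p_cal: np.ndarray, y_cal: np.ndarray) -> Recalibrator:
    """Pool-adjacent-violators recalibration; non-decreasing step map.

    The fitted step function is evaluated by linear interpolation between
    its knots, with out-of-range inputs clipped to the end values.
    """
    p_cal = np.asarray(p_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if np.ptp(p_cal) < 1e-12:
        level = float(np.mean(y_cal))
        return Recalibrator("isotonic", lambda p: np.full(np.asarray(p).shape, level))
    if len(np.unique(y_cal)) < 2:
        warnings.warn("degenerate calibration split: returning identity map", UserWarning)
        return Recalibrator("identity", lambda p: p)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(p_cal, y_cal)
    return Recalibrator("isotonic", iso.predict)


def calibration_split(
    X: pd.DataFrame, y: np.ndarray, fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split of development indices into (train, calibration)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    cal_parts = []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        n_cal = max(1, int(round(fraction * idx.size)))
        cal_parts.append(rng.choice(idx, size=n_cal, replace=False))
    cal = np.sort(np.concatenate(cal_parts))
    train = np.setdiff1d(np.arange(y.size), cal)
    return train, cal


def knn_minority_interpolation(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0, k: int = 5, experimental: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """EXPERIMENTAL minority interpolation (non-canonical SMOTE-like variant).

    New minority rows are uniform interpolations between a random minority
    row and one of its ``k`` nearest minority neighbours, added until the
    classes balance.  This is *not* a faithful SMOTE implementation (no
    special handling of categorical columns); it must be enabled
    explicitly with ``experimental=True``.
    """
    if not experimental:
        raise ValueError(
            "knn_minority_interpolation is experimental and non-canonical; "
            "pass experimental=True to acknowledge this"
        )
    y = np.asarray(y)
    minority, majority = _classes(y)
    if minority.size < 2:
        raise ValueError("need at least two minority rows to interpolate")
    rng = np.random.default_rng(seed)
    M = X.iloc[minority].to_numpy(dtype=float)
    n_new = majority.size - minority.size
    d2 = ((M[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbours = np.argsort(d2, axis=1)[:, : min(k, minority.size - 1)]
    base = rng.integers(0, minority.size, size=n_new)
    pick = neighbours[base, rng.integers(0, neighbours.shape[1], size=n_new)]
    t = rng.random((n_new, 1))
    synthetic = M[base] + t * (M[pick] - M[base])
    X_new = pd.concat(
        [X.reset_index(drop=True), pd.DataFrame(synthetic, columns=X.columns)],
        ignore_index=True,
    )
    label = int(y[minority[0]])
    y_new = np.concatenate([y, np.full(n_new, label, dtype=y.dtype)])
    return X_new, y_new
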