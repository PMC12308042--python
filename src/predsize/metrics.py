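"""Validation-metric suite: predictive accuracy, discrimination, calibration.

The suite evaluates a vector of predicted probabilities π̂ against the
true generating probabilities π (MAPE) and the observed binary outcomes
y (everything else):

* ``mape`` — mean |π̂ − π|.
* ``c_statistic`` — pairwise concordance, ties counted 1/2.
* ``delong_se`` — DeLong's structural-components standard error of Ĉ.
* ``calibration_in_the_large`` — mean(y) − mean(π̂); negative values
  indicate systematic overestimation.
* ``calibration_slope`` — slope of a logistic regression of y on
  logit(π̂); 1 is ideal, below 1 indicates overfitting.
* ``ici`` / ``e90`` — mean and 90th percentile of |ĉ(π̂) − π̂| where
  ĉ is a locally smoothed observed-event-rate curve.
* ``brier`` — mean (y − π̂)².

Tree-ensemble vote proportions can be exactly 0 or 1.  Following the
conventions adopted here, :func:`evaluate_all` clips π̂ to
[0.0001, 0.9999] for the C-statistic only, excludes boundary predictions
from all calibration measures (recording the count), and leaves MAPE and
the Brier score untouched.  Degenerate inputs yield NaN with a recorded
reason rather than an exception, so simulation replicates can proceed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "MetricSet",
    "mape",
    "c_statistic",
    "delong_se",
    "calibration_in_the_large",
    "calibration_slope",
    "ici",
    "e90",
    "ici_weighted",
    "brier",
    "evaluate_all",
]

#: clip applied to π̂ before C-statistic computation when exact 0/1 occur
BOUNDARY_CLIP = 1e-4
#: clamp applied to interior probabilities before taking logits
LOGIT_CLAMP = 1e-6

METRIC_NAMES = ("mape", "c_statistic", "delong_se", "citl", "cal_slope", "ici", "e90", "brier")


def _check_lengths(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")


def mape(p_hat: np.ndarray, p_true: np.ndarray) -> float:
    """Mean absolute prediction error against the true probabilities."""
    p_hat = np.asarray(p_hat, float)
    p_true = np.asarray(p_true, float)
    _check_lengths(p_hat, p_true)
    if p_hat.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(p_hat - p_true)))


def brier(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference between outcome and predicted probability."""
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y, float)
    _check_lengths(p_hat, y)
    return float(np.mean((y - p_hat) ** 2))


def c_statistic(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Concordance probability (AUROC) with tied predictions counted 1/2.

    Computed via midranks in O(n log n): with R_i the midrank of p̂_i
    among all n observations, C = (mean rank of events − (n₁+1)/2) / n₀.
    """
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y)
    _check_lengths(p_hat, y)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("C-statistic undefined: only one outcome class present")
    ranks = rankdata(p_hat)  # midranks
    return float((ranks[y == 1].mean() - (n1 + 1) / 2.0) / n0)


def _delong_components(p_hat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (events) and V01 (non-events)."""
    pos = p_hat[y == 1]
    neg = p_hat[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_se(p_hat: np.ndarray, y: np.ndarray) -> float:
    """DeLong's standard error of the empirical C-statistic."""
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y)
    _check_lengths(p_hat, y)
    m = int(np.sum(y == 1))
    n = int(np.sum(y == 0))
    if m < 2 or n < 2:
        raise ValueError("DeLong SE requires at least two events and two non-events")
    v10, v01, _ = _delong_components(p_hat, y)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return float(np.sqrt(var))


def calibration_in_the_large(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Observed event proportion minus mean predicted probability."""
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y, float)
    _check_lengths(p_hat, y)
    if p_hat.size == 0:
        raise ValueError("empty input")
    return float(np.mean(y) - np.mean(p_hat))


def _slope_with_reason(p_hat: np.ndarray, y: np.ndarray) -> tuple[float, str | None]:
    if len(p_hat) < 10:
        return float("nan"), "fewer than 10 subjects after boundary exclusion"
    if len(np.unique(y)) < 2:
        return float("nan"), "single outcome class after boundary exclusion"
    lo = logit(np.clip(p_hat, LOGIT_CLAMP, 1.0 - LOGIT_CLAMP))
    if np.ptp(lo) < 1e-12:
        return float("nan"), "degenerate: constant logit"
    try:
        model = sm.GLM(y, sm.add_constant(lo), family=sm.families.Binomial())
        res = model.fit()
        return float(res.params[1]), None
    except Exception as exc:  # noqa: BLE001 - degeneracy becomes a recorded reason
        return float("nan"), f"slope fit failed: {exc!r}"


def calibration_slope(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Slope of a logistic regression of y on logit(π̂); NaN when degenerate.

    Callers wanting the degeneracy reason should use :func:`evaluate_all`,
    which records it.
    """
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y)
    _check_lengths(p_hat, y)
    return _slope_with_reason(p_hat, y)[0]


def _smoothed_curve(p_hat: np.ndarray, y: np.ndarray, span: float = 0.75) -> np.ndarray:
    """Locally weighted observed-event-rate curve evaluated at each π̂."""
    delta = 0.001 * float(np.ptp(p_hat))
    # it=0: robustness iterations would downweight the binary outcomes as
    # outliers and bias the curve towards the majority class
    fitted = lowess(y, p_hat, frac=span, delta=delta, it=0, return_sorted=False)
    if np.any(~np.isfinite(fitted)):
        raise RuntimeError("lowess produced non-finite values")
    return np.clip(fitted, 0.0, 1.0)


def _binned_curve(p_hat: np.ndarray, y: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Fallback calibration curve: equal-frequency bin means."""
    order = np.argsort(p_hat, kind="stable")
    bins = np.array_split(order, min(n_bins, len(p_hat)))
    fitted = np.empty_like(p_hat, dtype=float)
    for idx in bins:
        fitted[idx] = float(np.mean(y[idx]))
    return fitted


def _calibration_abs_errors(p_hat: np.ndarray, y: np.ndarray) -> np.ndarray:
    try:
        curve = _smoothed_curve(p_hat, y)
    except Exception:
        curve = _binned_curve(p_hat, y)
    return np.abs(curve - p_hat)


def ici(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Integrated calibration index: mean |ĉ(π̂) − π̂| along a smoothed curve."""
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y, float)
    _check_lengths(p_hat, y)
    if len(p_hat) < 10:
        return float("nan")
    return float(np.mean(_calibration_abs_errors(p_hat, y)))


def e90(p_hat: np.ndarray, y: np.ndarray) -> float:
    """90th percentile of |ĉ(π̂) − π̂| along the smoothed calibration curve."""
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y, float)
    _check_lengths(p_hat, y)
    if len(p_hat) < 10:
        return float("nan")
    return float(np.percentile(_calibration_abs_errors(p_hat, y), 90))


def ici_weighted(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Secondary statistic: |y − π̂| averaged with weights equal to π̂.

    A literal reading of "weighted average of absolute differences with
    the predicted probabilities as weights"; reported alongside the
    smoothed-curve ICI, which is the primary definition here.
    """
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y, float)
    _check_lengths(p_hat, y)
    w = p_hat.sum()
    if w <= 0:
        return float("nan")
    return float(np.sum(p_hat * np.abs(y - p_hat)) / w)


@dataclass
class MetricSet:
    """One replicate's evaluation, with per-metric missingness reasons."""

    mape: float
    c_statistic: float
    delong_se: float
    citl: float
    cal_slope: float
    ici: float
    e90: float
    brier: float
    n_eval: int
    n_excluded_boundary: int
    reasons: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def to_rows(self, **labels) -> list[dict]:
        """Serialise to tidy rows: one per metric, with optional labels."""
        rows = []
        for name in METRIC_NAMES:
            rows.append(
                {
                    **labels,
                    "metric": name,
                    "value": getattr(self, name),
                    "reason": self.reasons.get(name),
                }
            )
        return rows


def evaluate_all(
    p_hat: np.ndarray,
    p_true: np.ndarray | None,
    y: np.ndarray,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> MetricSet:
    """Evaluate the full metric suite under the boundary-handling rules.

    MAPE and Brier use π̂ unchanged; the C-statistic and its DeLong SE use
    π̂ clipped to [0.0001, 0.9999]; calibration-in-the-large, slope, ICI
    and E90 are computed on the subset with π̂ strictly inside (0, 1),
    with the excluded count recorded.  ``metrics`` restricts which metrics
    are computed (the rest are NaN) — useful for large simulation runs
    where only a subset is needed.
    """
    p_hat = np.asarray(p_hat, float)
    y = np.asarray(y)
    _check_lengths(p_hat, y)
    values: dict[str, float] = {name: float("nan") for name in METRIC_NAMES}
    reasons: dict[str, str] = {}

    if "mape" in metrics:
        if p_true is None:
            reasons["mape"] = "true probabilities not supplied"
        else:
            values["mape"] = mape(p_hat, p_true)
    if "brier" in metrics:
        values["brier"] = brier(p_hat, y)

    clipped = np.clip(p_hat, BOUNDARY_CLIP, 1.0 - BOUNDARY_CLIP)
    if "c_statistic" in metrics or "delong_se" in metrics:
        try:
            if "c_statistic" in metrics:
                values["c_statistic"] = c_statistic(clipped, y)
            if "delong_se" in metrics:
                values["delong_se"] = delong_se(clipped, y)
        except ValueError as exc:
            for name in ("c_statistic", "delong_se"):
                if name in metrics:
                    reasons[name] = str(exc)

    interior = (p_hat > 0.0) & (p_hat < 1.0)
    n_excluded = int(np.sum(~interior))
    p_in, y_in = p_hat[interior], y[interior]
    calibration_requested = any(m in metrics for m in ("citl", "cal_slope", "ici", "e90"))
    if calibration_requested:
        if p_in.size == 0:
            for name in ("citl", "cal_slope", "ici", "e90"):
                if name in metrics:
                    reasons[name] = "all predictions on the boundary"
        else:
            if "citl" in metrics:
                values["citl"] = calibration_in_the_large(p_in, y_in)
            if "cal_slope" in metrics:
                slope, reason = _slope_with_reason(p_in, y_in)
                values["cal_slope"] = slope
                if reason:
                    reasons["cal_slope"] = reason
            for name, fn in (("ici", ici), ("e90", e90)):
                if name in metrics:
                    val = fn(p_in, y_in)
                    values[name] = val
                    if np.isnan(val):
                        reasons[name] = "too few interior predictions for the smoother"

    return MetricSet(
        **values,
        n_eval=len(p_hat),
        n_excluded_boundary=n_excluded,
        reasons=reasons,
    )
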