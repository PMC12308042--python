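"""The five analysis models behind a single probability-prediction contract.

* ``lr_main`` — maximum-likelihood logistic regression, linear main
  effects only (ordinal predictors enter as a linear score).
* ``lr_spline`` — logistic regression with each continuous predictor
  expanded by a natural cubic spline basis (df = 4, knots taken from the
  development sample).
* ``bagging`` — bootstrap-aggregated classification trees; predicted
  probability = proportion of trees voting for the event class, so exact
  0s and 1s are possible.
* ``random_forest`` — bagging with a random predictor subset at each
  tree; same vote-proportion probability semantics.
* ``boosting`` — stochastic gradient boosting with Bernoulli deviance;
  probabilities come from the additive log-odds ensemble and are strictly
  inside (0, 1).

Hyperparameter tuning follows a freeze-before-simulating protocol:
five-fold cross-validated Brier score averaged over a handful of
pre-simulation datasets, grid argmin, ties broken by least model
complexity.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .dgm import natural_spline_basis

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_KINDS",
    "FittedPredictor",
    "TuningResult",
    "fit_lr_main",
    "fit_lr_spline",
    "fit_bagging",
    "fit_random_forest",
    "fit_boosting",
    "fit_model",
    "default_hyperparameters",
    "default_grid",
    "tune_hyperparameters",
]

MODEL_KINDS = ("lr_main", "lr_spline", "bagging", "random_forest", "boosting")

#: Frozen desk-scale defaults used when the tuning protocol is not run.
#: Tree counts are half the full-scale defaults to keep simulation
#: experiments tractable on a single core; bagging/forest trees are grown
#: to purity so that vote proportions retain their 0/1-capable semantics.
_DESK_DEFAULTS: dict[str, dict[str, Any]] = {
    "lr_main": {},
    "lr_spline": {"df": 4},
    "bagging": {"n_trees": 50},
    "random_forest": {"n_trees": 50, "max_features": "sqrt"},
    "boosting": {"n_trees": 100, "learning_rate": 0.1, "max_depth": 2, "subsample": 0.5},
}


@dataclass
class FittedPredictor:
    """A trained analysis model exposing per-subject event probabilities."""

    kind: str
    predict_fn: Callable[[pd.DataFrame], np.ndarray]
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = np.asarray(self.predict_fn(X), dtype=float)
        if p.size and (p.min() < -1e-12 or p.max() > 1.0 + 1e-12):
            raise RuntimeError(f"{self.kind} produced probabilities outside [0, 1]")
        return np.clip(p, 0.0, 1.0)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("development data must contain both events and non-events")


def _as_matrix(X: pd.DataFrame) -> np.ndarray:
    return np.asarray(X, dtype=float)


def _fit_logistic(design: np.ndarray, y: np.ndarray, sample_weight=None) -> LogisticRegression:
    """Unpenalised ML fit with a weak-ridge fallback on (quasi-)separation."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000, tol=1e-8)
        est.fit(design, y, sample_weight=sample_weight)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning(
                "logistic fit did not converge (possible separation); "
                "refitting with a weak ridge penalty"
            )
            est = LogisticRegression(penalty="l2", C=1e4, solver="lbfgs", max_iter=2000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(design, y, sample_weight=sample_weight)
    return est


def fit_lr_main(X: pd.DataFrame, y: np.ndarray, sample_weight=None, **_: Any) -> FittedPredictor:
    """Maximum-likelihood logistic regression with linear main effects."""
    y = np.asarray(y)
    if X.shape[1] == 0:
        # intercept-only model: predicted probability = event fraction
        p0 = float(np.average(y, weights=sample_weight))
        return FittedPredictor("lr_main", lambda Xn: np.full(len(Xn), p0))
    _check_two_classes(y)
    est = _fit_logistic(_as_matrix(X), y, sample_weight)
    columns = list(X.columns)

    def predict(Xn: pd.DataFrame) -> np.ndarray:
        return est.predict_proba(_as_matrix(Xn[columns]))[:, 1]

    return FittedPredictor(
        "lr_main",
        predict,
        metadata={"coef": est.coef_[0].tolist(), "intercept": float(est.intercept_[0])},
    )


def fit_lr_spline(
    X: pd.DataFrame,
    y: np.ndarray,
    continuous: Sequence[str] | None = None,
    df: int = 4,
    sample_weight=None,
    **_: Any,
) -> FittedPredictor:
    """Logistic regression with natural-spline-expanded continuous predictors.

    Knots (interior at the 25/50/75th percentiles, boundary at min/max)
    are taken from the development sample and frozen into the predictor,
    so validation data are expanded on the same basis.  ``continuous``
    names the columns to expand; by default every float-typed column.
    """
    y = np.asarray(y)
    _check_two_classes(y)
    if continuous is None:
        continuous = [c for c in X.columns if X[c].dtype.kind == "f"]
    continuous = list(continuous)
    knots: dict[str, tuple[np.ndarray, tuple[float, float]]] = {}
    for name in continuous:
        x = X[name].to_numpy(dtype=float)
        interior = np.percentile(x, [25, 50, 75])
        knots[name] = (interior, (float(x.min()), float(x.max())))

    columns = list(X.columns)

    def expand(Xn: pd.DataFrame) -> np.ndarray:
        blocks = []
        for name in columns:
            x = Xn[name].to_numpy(dtype=float)
            if name in knots:
                interior, boundary = knots[name]
                blocks.append(
                    natural_spline_basis(x, df=df, interior_knots=interior, boundary_knots=boundary)
                )
            else:
                blocks.append(x[:, None])
        return np.hstack(blocks)

    est = _fit_logistic(expand(X), y, sample_weight)
    n_params = 1 + (len(columns) - len(continuous)) + df * len(continuous)

    def predict(Xn: pd.DataFrame) -> np.ndarray:
        return est.predict_proba(expand(Xn))[:, 1]

    return FittedPredictor(
        "lr_spline",
        predict,
        hyperparameters={"df": df},
        metadata={"n_params": n_params, "continuous": continuous},
    )


def _vote_fraction(forest, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the event class (exact 0/1 possible)."""
    votes = np.zeros(len(X))
    for tree in forest.estimators_:
        leaf_proba = tree.predict_proba(X)
        event_col = int(np.where(tree.classes_ == 1)[0][0]) if 1 in tree.classes_ else None
        if event_col is None:
            continue
        votes += (leaf_proba[:, event_col] > 0.5).astype(float)
        # exact .5 leaves split their vote
        votes += 0.5 * (leaf_proba[:, event_col] == 0.5)
    return votes / len(forest.estimators_)


def _fit_forest(
    kind: str, X: pd.DataFrame, y: np.ndarray, seed: int, n_trees: int, max_features, sample_weight=None
) -> FittedPredictor:
    _check_two_classes(np.asarray(y))
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        n_jobs=1,
        random_state=seed,
    )
    est.fit(_as_matrix(X), y, sample_weight=sample_weight)
    columns = list(X.columns)

    def predict(Xn: pd.DataFrame) -> np.ndarray:
        return _vote_fraction(est, _as_matrix(Xn[columns]))

    return FittedPredictor(
        kind,
        predict,
        hyperparameters={"n_trees": n_trees, "max_features": max_features},
        seed=seed,
        metadata={"n_trees": n_trees},
    )


def fit_bagging(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0, n_trees: int = 50, sample_weight=None, **_: Any
) -> FittedPredictor:
    """Bagged classification trees (all predictors considered at every split).

    Implemented as the all-features special case of the random forest, so
    a forest fitted with the full predictor subset and the same seed
    produces identical trees.
    """
    return _fit_forest("bagging", X, y, seed, n_trees, max_features=None, sample_weight=sample_weight)


def fit_random_forest(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_trees: int = 50,
    max_features: Any = "sqrt",
    sample_weight=None,
    **_: Any,
) -> FittedPredictor:
    """Random forest: bagging with a random predictor subset per split."""
    return _fit_forest(
        "random_forest", X, y, seed, n_trees, max_features=max_features, sample_weight=sample_weight
    )


def fit_boosting(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_trees: int = 100,
    learning_rate: float = 0.1,
    max_depth: int = 2,
    subsample: float = 0.5,
    sample_weight=None,
    **_: Any,
) -> FittedPredictor:
    """Stochastic gradient boosting on the log-odds scale.

    The ensemble is initialised at the event log-odds and updated
    additively, so predictions are strictly inside (0, 1).
    """
    _check_two_classes(np.asarray(y))
    est = GradientBoostingClassifier(
        n_estimators=n_trees,
        learning_rate=learning_rate,
        max_depth=max_depth,
        subsample=subsample,
        random_state=seed,
    )
    est.fit(_as_matrix(X), y, sample_weight=sample_weight)
    columns = list(X.columns)

    def predict(Xn: pd.DataFrame) -> np.ndarray:
        return est.predict_proba(_as_matrix(Xn[columns]))[:, 1]

    return FittedPredictor(
        "boosting",
        predict,
        hyperparameters={
            "n_trees": n_trees,
            "learning_rate": learning_rate,
            "max_depth": max_depth,
            "subsample": subsample,
        },
        seed=seed,
    )


_FITTERS: dict[str, Callable[..., FittedPredictor]] = {
    "lr_main": fit_lr_main,
    "lr_spline": fit_lr_spline,
    "bagging": fit_bagging,
    "random_forest": fit_random_forest,
    "boosting": fit_boosting,
}


def default_hyperparameters(kind: str) -> dict[str, Any]:
    return dict(_DESK_DEFAULTS[kind])


def fit_model(
    kind: str,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    hyperparameters: dict[str, Any] | None = None,
    sample_weight=None,
    **extra: Any,
) -> FittedPredictor:
    """Fit any of the five analysis models by kind name."""
    if kind not in _FITTERS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    hp = default_hyperparameters(kind)
    if hyperparameters:
        hp.update(hyperparameters)
    hp.update(extra)
    if kind in ("bagging", "random_forest", "boosting"):
        hp["seed"] = seed
    return _FITTERS[kind](X, y, sample_weight=sample_weight, **hp)


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------


def default_grid(kind: str, n_predictors: int) -> list[dict[str, Any]]:
    """Default hyperparameter grids searched before the main simulations."""
    if kind == "bagging":
        return [{"n_trees": t} for t in (100, 250, 500)]
    if kind == "random_forest":
        subset = sorted(
            {max(1, int(round(np.sqrt(n_predictors)))), max(1, n_predictors // 3), max(1, n_predictors // 2)}
        )
        return [
            {"n_trees": t, "max_features": m}
            for t in (100, 250, 500)
            for m in subset
        ]
    if kind == "boosting":
        return [
            {"n_trees": t, "max_depth": d, "learning_rate": lr, "subsample": 0.5}
            for t, d, lr in itertools.product((100, 250, 500), (1, 2, 3), (0.01, 0.1))
        ]
    return [{}]


def _complexity(kind: str, hp: dict[str, Any]) -> float:
    """Tie-break proxy: prefer fewer/shallower trees and larger shrinkage."""
    trees = hp.get("n_trees", 1)
    depth = hp.get("max_depth") or 25  # unrestricted trees treated as deep
    subset = hp.get("max_features")
    subset = 1.0 if subset in (None, "sqrt") else float(subset)
    return trees * depth * (1.0 / hp.get("learning_rate", 1.0)) * max(subset, 1.0)


@dataclass
class TuningResult:
    kind: str
    best: dict[str, Any]
    table: pd.DataFrame  # one row per grid point with mean CV Brier

    def to_json(self, path: str) -> None:
        payload = {
            "kind": self.kind,
            "best": self.best,
            "grid": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def tune_hyperparameters(
    kind: str,
    scenario_datasets: Sequence[tuple[pd.DataFrame, np.ndarray]],
    grid: Sequence[dict[str, Any]] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> TuningResult:
    """Grid search by cross-validated Brier score over pre-simulation datasets.

    For every grid point the model is fitted with ``folds``-fold
    stratified cross-validation on each dataset; the point with the lowest
    mean held-out Brier score wins, ties broken by least model complexity.
    Intended to be run once per scenario before the full simulations, with
    the winner frozen for every replicate.
    """
    if not scenario_datasets:
        raise ValueError("need at least one scenario dataset")
    if grid is None:
        grid = default_grid(kind, scenario_datasets[0][0].shape[1])
    if not grid:
        raise ValueError("empty hyperparameter grid")

    rows = []
    failures = []
    for point in grid:
        briers = []
        try:
            for d_idx, (X, y) in enumerate(scenario_datasets):
                y = np.asarray(y)
                splitter = StratifiedKFold(folds, shuffle=True, random_state=seed + d_idx)
                for train, test in splitter.split(X, y):
                    model = fit_model(
                        kind, X.iloc[train], y[train], seed=seed, hyperparameters=point
                    )
                    p = model.predict(X.iloc[test])
                    briers.append(float(np.mean((y[test] - p) ** 2)))
        except Exception as exc:  # noqa: BLE001 - grid points may legitimately fail
            failures.append((point, repr(exc)))
            continue
        rows.append({**point, "mean_brier": float(np.mean(briers)), "_complexity": _complexity(kind, point)})

    if not rows:
        raise RuntimeError(f"every grid point failed for {kind}: {failures}")
    table = pd.DataFrame(rows).sort_values(["mean_brier", "_complexity"], kind="stable")
    best = {
        k: v
        for k, v in table.iloc[0].items()
        if k not in ("mean_brier", "_complexity") and pd.notna(v)
    }
    # restore integer dtypes lost through the DataFrame round-trip
    for key in ("n_trees", "max_depth"):
        if key in best:
            best[key] = int(best[key])
    if "max_features" in best and not isinstance(best["max_features"], str):
        best["max_features"] = int(best["max_features"])
    return TuningResult(kind=kind, best=best, table=table.drop(columns="_complexity"))
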