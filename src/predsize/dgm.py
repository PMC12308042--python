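"""Data-generating mechanisms (DGMs) for the simulation experiments.

Each DGM freezes a probability rule over the full cohort: a candidate
analysis model is fitted to the cohort's base outcomes and its
predictions are adopted as the true probabilities π_i, from which a
frozen outcome vector y_i ~ Bernoulli(π_i) is simulated once.  Five
fitted kinds (main-effects logistic, spline logistic, bagging, random
forest, boosting) plus a *neutral* surface — a logistic model on
quintile-categorised continuous predictors with all two-way interactions,
matching none of the analysis models — are supported.

Tree-based DGMs produce vote-proportion probabilities, so π may contain
exact 0s and 1s; everything downstream tolerates this.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit

from .synthetic_cohort import (
    Cohort,
    PredictorSchema,
    calibrate_intercept,
    expected_c_of_probabilities,
    simulate_outcomes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DGM_KINDS",
    "FrozenDGM",
    "quintile_categorize",
    "natural_spline_basis",
    "neutral_design",
    "freeze_dgm",
]

DGM_KINDS = ("lr_main", "lr_spline", "bagging", "random_forest", "boosting", "neutral")


def quintile_categorize(x: np.ndarray) -> np.ndarray:
    """Assign each value to one of five equal-sized categories (0..4).

    Cut points sit at the empirical 20/40/60/80th percentiles; values
    exactly equal to a cut point fall into the lower category, so tied
    values always share a category.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least five observations to form quintiles")
    if np.unique(x).size < 5:
        raise ValueError("fewer than five distinct values: cannot form five categories")
    cuts = np.percentile(x, [20, 40, 60, 80])
    return np.searchsorted(cuts, x, side="left").astype(np.int64)


def natural_spline_basis(
    x: np.ndarray,
    df: int = 4,
    interior_knots: np.ndarray | None = None,
    boundary_knots: tuple[float, float] | None = None,
) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept column).

    Cubic between the boundary knots and linear beyond them.  By default
    the boundary knots sit at min/max of ``x`` and the ``df − 1`` interior
    knots at equally spaced percentiles (25/50/75 for df = 4).  Passing
    knots explicitly lets a model fitted on development data evaluate the
    same basis on new data.

    Uses the standard truncated-power construction: with sorted knots
    ξ_1 < … < ξ_K (K = df + 1) and
    d_k(x) = [(x−ξ_k)₊³ − (x−ξ_K)₊³] / (ξ_K − ξ_k), the basis is
    {x, d_1 − d_{K−1}, …, d_{K−2} − d_{K−1}}.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2")
    if interior_knots is None or boundary_knots is None:
        if np.unique(x).size < df + 2:
            raise ValueError("not enough distinct values to place the knots")
    if boundary_knots is None:
        boundary_knots = (float(x.min()), float(x.max()))
    if interior_knots is None:
        probs = np.linspace(0, 100, df + 1)[1:-1]  # 25/50/75 for df=4
        interior_knots = np.percentile(x, probs)
    knots = np.sort(np.r_[boundary_knots[0], np.asarray(interior_knots, float), boundary_knots[1]])
    if np.unique(knots).size != knots.size:
        raise ValueError("knots are not distinct; too few distinct data values")
    K = knots.size  # == df + 1

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[K - 1], 0.0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    d_last = d(K - 2)
    cols = [x] + [d(k) - d_last for k in range(K - 2)]
    return np.column_stack(cols)


def neutral_design(
    X: pd.DataFrame, schema: PredictorSchema
) -> tuple[pd.DataFrame, int]:
    """Design matrix of the neutral surface: categorised mains + all two-way interactions.

    Continuous predictors are quintile-categorised and dummy-encoded
    (4 columns each), binaries contribute one column, ordinals
    ``levels − 1`` dummies; every pair of columns from distinct predictors
    is multiplied to form the interaction block.  All-constant columns are
    dropped with a log record.  Returns the design (no intercept column)
    and the total parameter count including the intercept.
    """
    main_cols: dict[str, np.ndarray] = {}
    owner: dict[str, str] = {}
    for pred in schema.predictors:
        x = X[pred.name].to_numpy()
        if pred.kind == "continuous":
            cats = quintile_categorize(x)
            for level in range(1, 5):
                col = f"{pred.name}_q{level + 1}"
                main_cols[col] = (cats == level).astype(float)
                owner[col] = pred.name
        elif pred.kind == "binary":
            main_cols[pred.name] = x.astype(float)
            owner[pred.name] = pred.name
        else:  # ordinal dummies, reference = level 0
            n_levels = len(pred.level_probs)
            for level in range(1, n_levels):
                col = f"{pred.name}_l{level}"
                main_cols[col] = (x == level).astype(float)
                owner[col] = pred.name

    design = dict(main_cols)
    names = list(main_cols)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if owner[a] == owner[b]:
                continue
            design[f"{a}:{b}"] = main_cols[a] * main_cols[b]

    frame = pd.DataFrame(design, index=X.index)
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    if constant:
        logger.info("neutral design: dropping %d all-constant columns: %s", len(constant), constant)
        frame = frame.drop(columns=constant)
    n_params = frame.shape[1] + 1
    logger.info("neutral design: %d parameters including intercept", n_params)
    return frame, n_params


def _neutral_surface_probabilities(
    cohort: Cohort, seed: int, interaction_variance_fraction: float = 0.2
) -> tuple[np.ndarray, dict[str, Any]]:
    """Construct the neutral DGM's probabilities on the full cohort.

    Main-effect coefficients are inherited from the cohort's truth
    surface evaluated at per-category predictor means (so the categorised
    surface tracks the underlying one); interaction coefficients are drawn
    N(0, τ²) with τ set so the interaction block contributes the stated
    fraction of linear-predictor variance.  The intercept is recalibrated
    to the surface's target prevalence.
    """
    if cohort.surface is None:
        raise ValueError("neutral DGM requires a cohort with a truth surface")
    surface = cohort.surface
    design, n_params = neutral_design(cohort.X, cohort.schema)

    beta = np.zeros(design.shape[1])
    col_index = {c: j for j, c in enumerate(design.columns)}
    scale = surface.scale
    for pred in cohort.schema.predictors:
        x = cohort.X[pred.name].to_numpy()
        coef = surface.coefficients.get(pred.name, 0.0) * scale
        if pred.kind == "continuous":
            cats = quintile_categorize(x)
            ref_mean = float(x[cats == 0].mean())
            for level in range(1, 5):
                col = f"{pred.name}_q{level + 1}"
                if col in col_index:
                    beta[col_index[col]] = coef * (float(x[cats == level].mean()) - ref_mean)
        elif pred.kind == "binary":
            if pred.name in col_index:
                beta[col_index[pred.name]] = coef
        else:
            for level in range(1, len(pred.level_probs)):
                col = f"{pred.name}_l{level}"
                if col in col_index:
                    beta[col_index[col]] = coef * level

    M = design.to_numpy()
    lp_main = M @ beta
    interaction = np.array([":" in c for c in design.columns])
    rng = np.random.default_rng(seed)
    gamma = np.zeros_like(beta)
    gamma[interaction] = rng.standard_normal(int(interaction.sum()))
    lp_int = M @ gamma
    var_main = float(np.var(lp_main))
    var_int = float(np.var(lp_int))
    if var_int > 0 and var_main > 0:
        f = interaction_variance_fraction
        tau = np.sqrt(var_main * f / (1.0 - f) / var_int)
        gamma *= tau
        lp_int *= tau
    lp = lp_main + lp_int
    b0 = calibrate_intercept(lp, surface.target_prevalence)
    meta = {"n_params": n_params, "interaction_variance_fraction": interaction_variance_fraction}
    return expit(b0 + lp), meta


@dataclass
class FrozenDGM:
    """A frozen data-generating mechanism over a full cohort.

    ``pi`` are the generating probabilities, ``y`` the once-simulated
    frozen outcomes; ``true_c`` and ``prevalence`` are computed on the
    full data with the frozen outcomes, as used by the validation
    sample-size formula; ``expected_c`` is the sampling-noise-free
    expectation over outcome redraws.
    """

    kind: str
    pi: np.ndarray
    y: np.ndarray
    true_c: float
    expected_c: float
    prevalence: float
    seed: int
    model: Any = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def save(self, directory: str) -> None:
        """Persist probabilities/outcomes as delimited text plus JSON metadata."""
        os.makedirs(directory, exist_ok=True)
        pd.DataFrame({"pi": self.pi, "y": self.y}).to_csv(
            os.path.join(directory, "frozen.csv"), index=False
        )
        meta = {
            "kind": self.kind,
            "true_c": self.true_c,
            "expected_c": self.expected_c,
            "prevalence": self.prevalence,
            "seed": self.seed,
            **{k: v for k, v in self.metadata.items() if isinstance(v, (int, float, str))},
        }
        with open(os.path.join(directory, "frozen.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "FrozenDGM":
        table = pd.read_csv(os.path.join(directory, "frozen.csv"))
        with open(os.path.join(directory, "frozen.json")) as fh:
            meta = json.load(fh)
        return cls(
            kind=meta.pop("kind"),
            pi=table["pi"].to_numpy(),
            y=table["y"].to_numpy(dtype=np.int64),
            true_c=meta.pop("true_c"),
            expected_c=meta.pop("expected_c"),
            prevalence=meta.pop("prevalence"),
            seed=meta.pop("seed"),
            metadata=meta,
        )


def freeze_dgm(
    kind: str,
    cohort: Cohort,
    seed: int = 0,
    hyperparameters: dict[str, Any] | None = None,
) -> FrozenDGM:
    """Fit the generating model to the full cohort and freeze its predictions.

    The model of the given kind is fitted to the cohort's base outcomes
    (for ``neutral``, the surface is constructed rather than fitted), its
    predicted probabilities are adopted as the true π, and the frozen
    outcome vector is simulated once as Bernoulli(π).  The true
    C-statistic and prevalence are then computed from the full data with
    the frozen outcomes.
    """
    from .metrics import c_statistic  # local import to avoid a cycle
    from .model_zoo import fit_model

    if kind not in DGM_KINDS:
        raise ValueError(f"unknown DGM kind {kind!r}; expected one of {DGM_KINDS}")

    model = None
    metadata: dict[str, Any] = {}
    try:
        if kind == "neutral":
            pi, metadata = _neutral_surface_probabilities(cohort, seed)
        else:
            model = fit_model(kind, cohort.X, cohort.y, seed=seed, hyperparameters=hyperparameters)
            pi = model.predict(cohort.X)
    except Exception as exc:
        raise RuntimeError(f"failed to build {kind!r} DGM: {exc}") from exc

    y = simulate_outcomes(pi, seed + 1_000_003)
    prevalence = float(np.mean(y))
    interior = np.clip(pi, 1e-4, 1.0 - 1e-4)  # guard exact-0/1 vote proportions
    true_c = c_statistic(interior, y) if 0 < y.sum() < y.size else float("nan")
    expected_c = expected_c_of_probabilities(pi)
    return FrozenDGM(
        kind=kind,
        pi=pi,
        y=y,
        true_c=true_c,
        expected_c=expected_c,
        prevalence=prevalence,
        seed=seed,
        model=model,
        metadata=metadata,
    )
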