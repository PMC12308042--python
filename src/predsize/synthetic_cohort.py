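"""Synthetic patient-cohort generator with calibrated logistic truth surfaces.

Covariates are drawn through a Gaussian copula: a latent multivariate
normal with a declared correlation matrix is mapped margin-by-margin to
the declared predictor type (continuous, binary, ordinal).  A logistic
truth surface then assigns every subject a true event probability π_i,
with its intercept calibrated to a target prevalence and its non-intercept
coefficients rescaled to a target (expected) C-statistic; outcomes are
drawn as y_i ~ Bernoulli(π_i).

Two ready-made configurations emulate the structure of large
cardiovascular registries:

* :func:`minap_like_schema` — an acute-coronary-syndrome-like cohort with
  10 predictors (4 continuous, 5 binary, 1 ordinal), outcome prevalence
  0.063 and strong discrimination (C ≈ 0.86); predictor–outcome relations
  are linear on the log-odds scale.
* :func:`hf_like_schema` — a heart-failure-like cohort with 17 predictors
  (9 continuous, 8 binary), prevalence 0.113 and C ≈ 0.81, with genuinely
  non-linear effects for five of the continuous predictors.

Marginal shapes, correlations and effect sizes of the real registries are
not public; the defaults here are declared, realistic choices (standard
normal continuous margins, mild exchangeable latent correlation), not
estimates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "Predictor",
    "PredictorSchema",
    "TruthSurfaceSpec",
    "Cohort",
    "minap_like_schema",
    "hf_like_schema",
    "minap_like_surface",
    "hf_like_surface",
    "generate_covariates",
    "calibrate_intercept",
    "expected_c_of_probabilities",
    "calibrate_discrimination",
    "simulate_outcomes",
    "make_cohort",
]

_TRANSFORMS = {
    "identity": lambda x: x,
    # centred quadratic: U-shaped risk (e.g. blood pressure, BMI)
    "quadratic": lambda x: x * x - 1.0,
    # saturating log: diminishing effect at high values (e.g. biomarkers)
    "log_bend": lambda x: np.log1p(np.exp(x)) - np.log(2.0),
    # piecewise-linear bend at 0: threshold-type effect
    "bend": lambda x: np.where(x > 0.0, 1.5 * x, 0.5 * x),
}


@dataclass(frozen=True)
class Predictor:
    """One predictor's marginal description.

    ``kind`` is ``"continuous"`` (params: mean, sd), ``"binary"``
    (params: prevalence) or ``"ordinal"`` (params: level probabilities,
    levels coded 0..L−1).
    """

    name: str
    kind: str
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    level_probs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "binary" and not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"{self.name}: binary prevalence must lie in (0, 1)")
        if self.kind == "ordinal":
            probs = np.asarray(self.level_probs, dtype=float)
            if probs.size < 2 or np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(
                    f"{self.name}: ordinal level probabilities must be positive and sum to 1"
                )


@dataclass(frozen=True)
class PredictorSchema:
    """Predictor margins plus the latent (copula) correlation matrix."""

    predictors: tuple[Predictor, ...]
    correlation: np.ndarray

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        p = len(self.predictors)
        if corr.shape != (p, p):
            raise ValueError(f"correlation matrix shape {corr.shape} != ({p}, {p})")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        object.__setattr__(self, "correlation", corr)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.predictors]

    def continuous_names(self) -> list[str]:
        return [p.name for p in self.predictors if p.kind == "continuous"]

    def by_name(self, name: str) -> Predictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass(frozen=True)
class TruthSurfaceSpec:
    """A logistic probability-generating rule over a predictor schema.

    ``coefficients`` maps predictor names to log-odds slopes (ordinal
    predictors enter as a linear score over level codes); ``transforms``
    optionally maps continuous predictor names to a named non-linear
    transform applied before the slope.  ``scale`` multiplies every
    non-intercept coefficient and is the handle used to calibrate
    discrimination.
    """

    coefficients: dict[str, float]
    intercept: float = 0.0
    scale: float = 1.0
    transforms: dict[str, str] = field(default_factory=dict)
    target_prevalence: float = 0.5
    target_c: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.target_prevalence <= 0.5):
            raise ValueError("target_prevalence must lie in (0, 0.5]")
        if not (0.5 < self.target_c < 1.0):
            raise ValueError("target_c must lie in (0.5, 1)")
        for name, tag in self.transforms.items():
            if tag not in _TRANSFORMS:
                raise ValueError(f"unknown transform {tag!r} for predictor {name!r}")

    def linear_predictor(self, table: pd.DataFrame, include_intercept: bool = False) -> np.ndarray:
        lp = np.zeros(len(table))
        for name, beta in self.coefficients.items():
            x = table[name].to_numpy(dtype=float)
            tag = self.transforms.get(name, "identity")
            lp += beta * _TRANSFORMS[tag](x)
        lp *= self.scale
        if include_intercept:
            lp += self.intercept
        return lp

    def probabilities(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table, include_intercept=True))


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: covariates, true probabilities and outcomes."""

    X: pd.DataFrame
    pi: np.ndarray
    y: np.ndarray
    schema: PredictorSchema
    surface: TruthSurfaceSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.X)
        if len(self.pi) != n or len(self.y) != n:
            raise ValueError("X, pi and y must have equal lengths")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.y))

    @property
    def expected_prevalence(self) -> float:
        return float(np.mean(self.pi))

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["pi_true"] = self.pi
        out["y"] = self.y
        return out

    def write(self, table_path: str, sidecar_path: str | None = None) -> None:
        """Write the cohort as a delimited text table plus a JSON sidecar."""
        self.to_frame().to_csv(table_path, index=False)
        if sidecar_path is not None:
            meta = {
                "n": len(self),
                "seed": self.seed,
                "achieved_prevalence": self.prevalence,
                "expected_prevalence": self.expected_prevalence,
                "expected_c": expected_c_of_probabilities(self.pi),
                "predictors": [
                    {"name": p.name, "kind": p.kind} for p in self.schema.predictors
                ],
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# Ready-made registry-like configurations
# ---------------------------------------------------------------------------


def _exchangeable_correlation(kinds: list[str], within: float = 0.2, across: float = 0.1) -> np.ndarray:
    """Mild collinearity: `within` between same-kind pairs, `across` otherwise."""
    p = len(kinds)
    corr = np.full((p, p), across)
    for i in range(p):
        for j in range(p):
            if kinds[i] == kinds[j]:
                corr[i, j] = within
        corr[i, i] = 1.0
    return corr


def minap_like_schema() -> PredictorSchema:
    """10 predictors (4 continuous, 5 binary, 1 ordinal), ACS-registry-like."""
    preds = (
        [Predictor(f"cont{i + 1}", "continuous") for i in range(4)]
        + [
            Predictor("bin1", "binary", prevalence=0.45),
            Predictor("bin2", "binary", prevalence=0.30),
            Predictor("bin3", "binary", prevalence=0.20),
            Predictor("bin4", "binary", prevalence=0.15),
            Predictor("bin5", "binary", prevalence=0.55),
        ]
        + [Predictor("ord1", "ordinal", level_probs=(0.5, 0.3, 0.2))]
    )
    kinds = [p.kind for p in preds]
    return PredictorSchema(tuple(preds), _exchangeable_correlation(kinds))


def minap_like_surface() -> TruthSurfaceSpec:
    """Linear truth surface targeting prevalence 0.063 and C ≈ 0.86."""
    coeffs = {
        "cont1": 1.0,
        "cont2": 0.8,
        "cont3": -0.6,
        "cont4": 0.5,
        "bin1": 0.7,
        "bin2": -0.5,
        "bin3": 0.6,
        "bin4": 0.8,
        "bin5": -0.4,
        "ord1": 0.5,
    }
    return TruthSurfaceSpec(coefficients=coeffs, target_prevalence=0.063, target_c=0.86)


def hf_like_schema() -> PredictorSchema:
    """17 predictors (9 continuous, 8 binary), heart-failure-registry-like."""
    preds = [Predictor(f"cont{i + 1}", "continuous") for i in range(9)] + [
        Predictor("bin1", "binary", prevalence=0.50),
        Predictor("bin2", "binary", prevalence=0.35),
        Predictor("bin3", "binary", prevalence=0.25),
        Predictor("bin4", "binary", prevalence=0.20),
        Predictor("bin5", "binary", prevalence=0.15),
        Predictor("bin6", "binary", prevalence=0.40),
        Predictor("bin7", "binary", prevalence=0.30),
        Predictor("bin8", "binary", prevalence=0.10),
    ]
    kinds = [p.kind for p in preds]
    return PredictorSchema(tuple(preds), _exchangeable_correlation(kinds))


def hf_like_surface() -> TruthSurfaceSpec:
    """Truth surface with non-linear continuous effects, prevalence 0.113, C ≈ 0.81."""
    coeffs = {
        "cont1": 0.8,
        "cont2": 0.6,
        "cont3": -0.5,
        "cont4": 0.5,
        "cont5": 0.6,
        "cont6": -0.4,
        "cont7": 0.3,
        "cont8": 0.3,
        "cont9": -0.3,
        "bin1": 0.5,
        "bin2": -0.4,
        "bin3": 0.5,
        "bin4": 0.6,
        "bin5": 0.4,
        "bin6": -0.3,
        "bin7": 0.3,
        "bin8": 0.5,
    }
    transforms = {
        "cont1": "quadratic",
        "cont2": "log_bend",
        "cont3": "bend",
        "cont4": "quadratic",
        "cont5": "log_bend",
    }
    return TruthSurfaceSpec(
        coefficients=coeffs,
        transforms=transforms,
        target_prevalence=0.113,
        target_c=0.81,
    )


# ---------------------------------------------------------------------------
# Generation and calibration
# ---------------------------------------------------------------------------


def generate_covariates(schema: PredictorSchema, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` subjects from the schema's Gaussian copula.

    A latent N(0, R) draw is mapped margin-by-margin: continuous margins
    by location/scale, binary margins by thresholding at the prevalence
    quantile, ordinal margins by thresholding at cumulative-probability
    quantiles.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    corr = schema.correlation
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigvals[0]:.3g}):\n{corr}"
        )
    rng = np.random.default_rng(seed)
    # eigendecomposition square root: tolerates exactly-singular PSD matrices
    vals, vecs = np.linalg.eigh(corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n, len(schema.predictors))) @ root.T

    cols: dict[str, np.ndarray] = {}
    for j, pred in enumerate(schema.predictors):
        zj = z[:, j]
        if pred.kind == "continuous":
            cols[pred.name] = pred.mean + pred.sd * zj
        elif pred.kind == "binary":
            cols[pred.name] = (zj > norm.ppf(1.0 - pred.prevalence)).astype(np.int64)
        else:  # ordinal
            cum = np.cumsum(pred.level_probs)[:-1]
            cuts = norm.ppf(cum)
            cols[pred.name] = np.searchsorted(cuts, zj, side="left").astype(np.int64)
    return pd.DataFrame(cols)


def calibrate_intercept(linear_predictor: np.ndarray, target_prevalence: float) -> float:
    """Intercept β₀ such that mean(expit(β₀ + lp)) matches the target.

    Solved by root bracketing; accurate to within 1e-6 on the prevalence
    scale (well inside the 1e-4 contract).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target prevalence must lie in (0, 1)")

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + lp))) - target_prevalence

    lo, hi = -5.0, 5.0
    for _ in range(20):
        if gap(lo) < 0.0 < gap(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise ValueError("could not bracket the intercept; degenerate linear predictor")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def expected_c_of_probabilities(pi: np.ndarray) -> float:
    """Expected C-statistic when outcomes are Bernoulli(π).

    For outcomes drawn independently as y_i ~ Bernoulli(π_i), the expected
    concordance (ties counted 1/2) is

        Σ_{i≠j} π_i (1−π_j) [ I(π_i > π_j) + ½ I(π_i = π_j) ]
        ────────────────────────────────────────────────────
                    Σ_{i≠j} π_i (1−π_j)

    computed here in O(N log N) via sorting and prefix sums over tie
    groups; exact up to floating point.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.size < 2:
        raise ValueError("need at least two subjects")
    if np.any((pi < 0.0) | (pi > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    s1 = pi.sum()
    s0 = (1.0 - pi).sum()
    self_pairs = float(np.sum(pi * (1.0 - pi)))
    denom = s1 * s0 - self_pairs
    if denom <= 0.0:
        raise ValueError("degenerate probabilities: no discordant-capable pairs")

    values, counts = np.unique(pi, return_counts=True)
    group_one = values * counts          # Σ π within each tie group
    group_zero = (1.0 - values) * counts  # Σ (1−π) within each tie group
    cum_zero_below = np.concatenate(([0.0], np.cumsum(group_zero)))[:-1]
    num = float(np.sum(group_one * cum_zero_below))
    # within-group unordered pairs, counted half
    within = values * (1.0 - values) * counts * (counts - 1)
    num += 0.5 * float(np.sum(within))
    return num / denom


def calibrate_discrimination(
    spec: TruthSurfaceSpec,
    covariates: pd.DataFrame,
    tol: float = 0.005,
    max_scale: float = 50.0,
) -> TruthSurfaceSpec:
    """Rescale non-intercept coefficients until the expected C hits the target.

    Bisection on the coefficient scale factor, recalibrating the intercept
    to the target prevalence at every step (the expected C is evaluated on
    the implied true probabilities, so no outcome-sampling noise enters).
    If the target is unattainable within ``max_scale`` a warning is issued
    and the best achieved surface returned.
    """
    base_lp = replace(spec, scale=1.0).linear_predictor(covariates)

    def achieved(scale: float) -> float:
        lp = scale * base_lp
        if np.allclose(lp, lp[0]):
            return 0.5
        b0 = calibrate_intercept(lp, spec.target_prevalence)
        return expected_c_of_probabilities(expit(b0 + lp))

    if abs(spec.target_c - 0.5) < 1e-12:
        b0 = calibrate_intercept(np.zeros(len(covariates)), spec.target_prevalence)
        return replace(spec, scale=0.0, intercept=b0)

    lo, hi = 0.0, 1.0
    while achieved(hi) < spec.target_c:
        hi *= 2.0
        if hi > max_scale:
            c_best = achieved(max_scale)
            warnings.warn(
                f"target C {spec.target_c} unattainable on this schema; "
                f"best achieved C = {c_best:.4f} at scale {max_scale}",
                UserWarning,
                stacklevel=2,
            )
            hi = max_scale
            break
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if achieved(mid) < spec.target_c:
            lo = mid
        else:
            hi = mid
        if abs(achieved(0.5 * (lo + hi)) - spec.target_c) < 0.2 * tol:
            break
    scale = 0.5 * (lo + hi)
    b0 = calibrate_intercept(scale * base_lp, spec.target_prevalence)
    return replace(spec, scale=scale, intercept=b0)


def simulate_outcomes(pi: np.ndarray, seed: int) -> np.ndarray:
    """Independent Bernoulli(π) outcome draws; deterministic given seed."""
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0.0) | (pi > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(pi.size) < pi).astype(np.int64)


def make_cohort(kind: str = "minap", n: int = 50_000, seed: int = 0) -> Cohort:
    """Generate a full calibrated cohort of the given kind.

    ``kind`` is ``"minap"`` (linear surface, p = 0.063, C ≈ 0.86) or
    ``"hf"`` (non-linear surface, p = 0.113, C ≈ 0.81).  The default full
    cohort size of 50,000 is a desk-scale stand-in for registry-sized
    data; pass a smaller ``n`` for faster experiments.
    """
    if kind == "minap":
        schema, surface = minap_like_schema(), minap_like_surface()
    elif kind == "hf":
        schema, surface = hf_like_schema(), hf_like_surface()
    else:
        raise ValueError(f"unknown cohort kind {kind!r}; expected 'minap' or 'hf'")
    X = generate_covariates(schema, n, seed)
    surface = calibrate_discrimination(surface, X)
    pi = surface.probabilities(X)
    y = simulate_outcomes(pi, seed + 1)
    return Cohort(X=X, pi=pi, y=y, schema=schema, surface=surface, seed=seed)
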