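"""Closed-form sample-size calculators for risk prediction models.

Two calculators are provided:

* :func:`n_dev_for_mape` — minimum development sample size so that a
  logistic prediction model with ``k`` candidate predictor parameters and
  anticipated outcome proportion ``p`` attains a target mean absolute
  prediction error (MAPE) against the true event probabilities.
* :func:`n_val_for_c_precision` — minimum external-validation sample size
  so that the estimated concordance statistic (C-statistic / AUROC) of a
  model with anticipated discrimination ``C`` has a target standard error.

The validation calculator assumes an approximately normally distributed
linear predictor and involves Owen's T function,

    T(h, a) = (1/2π) ∫₀ᵃ exp(−h²(1+x²)/2) / (1+x²) dx,

evaluated here by adaptive quadrature on the defining integral
(:func:`owens_t`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "DevSampleSizeRequest",
    "ValSampleSizeRequest",
    "SampleSizeResult",
    "OWENS_T_SECOND_ARG",
    "owens_t",
    "c_variance_numerator",
    "n_dev_for_mape",
    "n_val_for_c_precision",
    "expected_epv",
]

#: Second argument of Owen's T in the C-statistic variance expression.
#: Under a normally distributed linear predictor the closed form uses
#: a = 1/sqrt(3); exposed so callers can override it.
OWENS_T_SECOND_ARG: float = 1.0 / math.sqrt(3.0)


@dataclass(frozen=True)
class DevSampleSizeRequest:
    """Inputs to the MAPE-targeting development sample-size formula.

    Parameters
    ----------
    prevalence:
        Anticipated outcome proportion ``p``; the formula is stated for
        ``0 < p <= 0.5`` (code the outcome so the event is the rarer class).
    k:
        Number of candidate predictor parameters (>= 1).  Non-linear terms
        (e.g. spline basis columns) each count as one parameter.
    target_mape:
        Target mean absolute prediction error, on the probability scale.
    """

    prevalence: float
    k: int
    target_mape: float

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence <= 0.5):
            raise ValueError(
                f"prevalence must lie in (0, 0.5], got {self.prevalence!r}; "
                "code the outcome so that the event is the minority class"
            )
        if int(self.k) != self.k or self.k < 1:
            raise ValueError(f"k must be an integer >= 1, got {self.k!r}")
        if not (0.0 < self.target_mape < 1.0):
            raise ValueError(f"target_mape must lie in (0, 1), got {self.target_mape!r}")
        if self.target_mape >= self.prevalence:
            warnings.warn(
                "target_mape >= prevalence: a MAPE target this loose is "
                "unlikely to be meaningful relative to the outcome prevalence",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ValSampleSizeRequest:
    """Inputs to the C-statistic-precision validation sample-size formula.

    Parameters
    ----------
    anticipated_c:
        Anticipated C-statistic of the model under validation, in (0.5, 1).
    prevalence:
        Anticipated outcome proportion in the validation population, (0, 1).
    target_se:
        Target standard error of the estimated C-statistic (> 0); the
        formula targets its square, the variance.
    """

    anticipated_c: float
    prevalence: float
    target_se: float

    def __post_init__(self) -> None:
        if not (0.5 < self.anticipated_c < 1.0):
            raise ValueError(
                f"anticipated_c must lie strictly in (0.5, 1), got {self.anticipated_c!r}"
            )
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence!r}")
        if not self.target_se > 0.0:
            raise ValueError(f"target_se must be positive, got {self.target_se!r}")


@dataclass(frozen=True)
class SampleSizeResult:
    """A computed sample size with events-per-variable accounting.

    ``epv`` is ``n * p / k`` rounded to one decimal for development
    requests and ``None`` for validation requests (which have no parameter
    count).  ``n_events`` is the anticipated event count ``round(n * p)``.
    """

    n: int
    n_events: int
    epv: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")
        if self.n_events < 0:
            raise ValueError(f"n_events must be >= 0, got {self.n_events!r}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def owens_t(h: float, a: float) -> float:
    """Owen's T function by adaptive quadrature on the defining integral.

    Accurate to roughly 1e-10 absolute.  ``T(h, 0) = 0`` and
    ``T(0, a) = arctan(a) / (2π)`` hold exactly in the limit of the
    quadrature tolerance.
    """
    if not (math.isfinite(h) and math.isfinite(a)):
        raise ValueError(f"owens_t requires finite arguments, got h={h!r}, a={a!r}")
    if a == 0.0:
        return 0.0

    def integrand(x: float) -> float:
        return math.exp(-0.5 * h * h * (1.0 + x * x)) / (1.0 + x * x)

    value, _ = integrate.quad(integrand, 0.0, a, epsabs=1e-12, epsrel=1e-12, limit=200)
    return value / (2.0 * math.pi)


def c_variance_numerator(c: float, second_arg: float = OWENS_T_SECOND_ARG) -> float:
    """Numerator of the validation-variance expression: C − 2·T(Φ⁻¹(C), a) − C².

    Strictly positive on C ∈ (0.5, 1); equals 1/12 in the C → 0.5 limit
    (since T(0, 1/√3) = arctan(1/√3)/(2π) = 1/12) and tends to 0 as C → 1.
    """
    if not (0.5 < c < 1.0):
        raise ValueError(f"C must lie strictly in (0.5, 1), got {c!r}")
    return c - 2.0 * owens_t(norm.ppf(c), second_arg) - c * c


def n_dev_for_mape(req: DevSampleSizeRequest) -> SampleSizeResult:
    """Development sample size targeting a mean absolute prediction error.

    Returns the smallest integer ``n`` with

        n >= exp((−0.508 + 0.259·ln p + 0.504·ln k − ln MAPE) / 0.544),

    i.e. the closed-form requirement rounded up, together with the implied
    event count and events per variable.
    """
    p, k, mape = req.prevalence, req.k, req.target_mape
    exponent = (-0.508 + 0.259 * math.log(p) + 0.504 * math.log(k) - math.log(mape)) / 0.544
    n = int(math.ceil(math.exp(exponent)))
    return SampleSizeResult(n=n, n_events=_round_half_up(n * p), epv=expected_epv(n, p, k))


def n_val_for_c_precision(
    req: ValSampleSizeRequest, second_arg: float = OWENS_T_SECOND_ARG
) -> SampleSizeResult:
    """External-validation sample size for a target SE of the C-statistic.

    ``n = ceil( (C − 2·T(Φ⁻¹(C), 1/√3) − C²) / (p·(1−p)·se²) )``; exactly
    inversely proportional to the squared target standard error.
    """
    numerator = c_variance_numerator(req.anticipated_c, second_arg=second_arg)
    p, se = req.prevalence, req.target_se
    n = int(math.ceil(numerator / (p * (1.0 - p) * se * se)))
    return SampleSizeResult(n=n, n_events=_round_half_up(n * p), epv=None)


def expected_epv(n: int, p: float, k: int) -> float:
    """Events per variable, ``n·p/k``, rounded to one decimal."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p!r}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k!r}")
    return float(np.round(n * p / k, 1))
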