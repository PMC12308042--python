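"""Simulation engines for the two sample-size evaluation experiments.

*Development experiment* (:func:`run_aim1`): with a frozen DGM over a
full cohort, each replicate draws a development sample of size ``n_dev``
(computed from the MAPE-targeting formula) with replacement, fits every
analysis model, and evaluates it on the subjects never drawn, against the
frozen true probabilities and outcomes.

*External-validation experiment* (:func:`run_aim2`): the validation
sample size is computed from the C-precision formula using the frozen
DGM's true C and prevalence; each replicate draws a stratified validation
sample with the implied number of events and records the empirical
C-statistic of the DGM's own predictions and its DeLong standard error.

Replicate seeds are spawned from the master seed through
``numpy.random.SeedSequence`` with a counter key, so every replicate is
independently reproducible and a full run is byte-identical given the
same configuration and master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dgm import FrozenDGM, freeze_dgm
from .imbalance import cost_weights, oversample, undersample
from .metrics import METRIC_NAMES, evaluate_all
from .model_zoo import fit_model
from .sample_size import (
    DevSampleSizeRequest,
    ValSampleSizeRequest,
    n_dev_for_mape,
    n_val_for_c_precision,
)
from .synthetic_cohort import Cohort, make_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "Aim1Scenario",
    "Aim2Scenario",
    "run_aim1",
    "run_aim2",
    "summarize",
    "load_scenario",
]

#: Desk-scale defaults: cohort of 20,000 and 100 replicates keep a full
#: scenario in the minutes range on one core; the registry-scale setup
#: (N ≈ 50,000, R = 1000) is available through configuration.
DESK_N = 20_000
DESK_R = 100


@dataclass(frozen=True)
class Aim1Scenario:
    """Configuration of one development-sample-size experiment."""

    cohort: str = "minap"  # "minap" or "hf"
    dgm: str = "lr_main"
    target_mapes: tuple[float, ...] = (0.02, 0.015, 0.01, 0.007, 0.005)
    models: tuple[str, ...] = ("lr_main", "bagging", "random_forest", "boosting")
    replicates: int = DESK_R
    n_full: int = DESK_N
    master_seed: int = 0
    k: int | None = None  # candidate parameter count; schema default if None
    metrics: tuple[str, ...] = METRIC_NAMES
    resampling: str = "none"
    cost_ratio: float = 1.0
    model_hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")

    @property
    def k_effective(self) -> int:
        if self.k is not None:
            return self.k
        return {"minap": 10, "hf": 44}[self.cohort]

    @property
    def prevalence(self) -> float:
        return {"minap": 0.063, "hf": 0.113}[self.cohort]


@dataclass(frozen=True)
class Aim2Scenario:
    """Configuration of one external-validation experiment."""

    cohort: str = "minap"
    dgm: str = "lr_main"
    target_ses: tuple[float, ...] = (0.010, 0.025)
    replicates: int = 200
    n_full: int = DESK_N
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")


def _replicate_seed(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


def _prepare(scenario, cohort: Cohort | None, frozen: FrozenDGM | None):
    if cohort is None:
        cohort = make_cohort(scenario.cohort, n=scenario.n_full, seed=scenario.master_seed)
    if frozen is None:
        frozen = freeze_dgm(scenario.dgm, cohort, seed=scenario.master_seed)
    if len(cohort) != len(frozen.pi):
        raise ValueError("frozen DGM does not match the cohort size")
    return cohort, frozen


def run_aim1(
    scenario: Aim1Scenario,
    cohort: Cohort | None = None,
    frozen: FrozenDGM | None = None,
) -> pd.DataFrame:
    """Run the development experiment; returns tidy long-format results.

    One row per (target MAPE, replicate, model, metric) with columns
    ``cohort, dgm, model, target_mape, n_dev, n_valid, replicate, metric,
    value, reason``.  Model failures inside a replicate are recorded as
    missing-with-reason rows and the engine continues.
    """
    cohort, frozen = _prepare(scenario, cohort, frozen)
    n_total = len(cohort)
    rows: list[dict] = []
    for t_idx, target in enumerate(scenario.target_mapes):
        req = DevSampleSizeRequest(scenario.prevalence, scenario.k_effective, target)
        n_dev = n_dev_for_mape(req).n
        if n_dev >= n_total:
            raise ValueError(
                f"n_dev={n_dev} for target MAPE {target} is not smaller than the "
                f"full cohort (N={n_total}); increase n_full"
            )
        t0 = time.monotonic()
        for rep in range(scenario.replicates):
            logger.debug("aim1 target %.3g replicate %d/%d", target, rep + 1, scenario.replicates)
            rng = _replicate_seed(scenario.master_seed, t_idx, rep)
            drawn = rng.integers(0, n_total, size=n_dev)
            in_dev = np.zeros(n_total, dtype=bool)
            in_dev[drawn] = True
            valid_idx = np.flatnonzero(~in_dev)
            X_dev = cohort.X.iloc[drawn].reset_index(drop=True)
            y_dev = frozen.y[drawn]
            X_val = cohort.X.iloc[valid_idx]
            pi_val = frozen.pi[valid_idx]
            y_val = frozen.y[valid_idx]

            X_fit, y_fit, weights = X_dev, y_dev, None
            resample_seed = int(rng.integers(0, 2**31 - 1))
            if scenario.resampling == "undersample":
                X_fit, y_fit = undersample(X_dev, y_dev, seed=resample_seed)
            elif scenario.resampling == "oversample":
                X_fit, y_fit = oversample(X_dev, y_dev, seed=resample_seed)
            elif scenario.resampling == "class_weight":
                weights = cost_weights(y_dev, scenario.cost_ratio)
            elif scenario.resampling != "none":
                raise ValueError(f"unknown resampling strategy {scenario.resampling!r}")

            labels = {
                "cohort": scenario.cohort,
                "dgm": scenario.dgm,
                "target_mape": target,
                "n_dev": n_dev,
                "n_valid": int(valid_idx.size),
                "replicate": rep,
            }
            for model_kind in scenario.models:
                model_seed = int(rng.integers(0, 2**31 - 1))
                try:
                    model = fit_model(
                        model_kind,
                        X_fit,
                        y_fit,
                        seed=model_seed,
                        hyperparameters=scenario.model_hyperparameters.get(model_kind),
                        sample_weight=weights,
                    )
                    p_hat = model.predict(X_val)
                    ms = evaluate_all(p_hat, pi_val, y_val, metrics=scenario.metrics)
                    rows.extend(ms.to_rows(model=model_kind, **labels))
                except Exception as exc:  # noqa: BLE001 - replicate-level resilience
                    logger.warning("replicate %d model %s failed: %r", rep, model_kind, exc)
                    for metric in scenario.metrics:
                        rows.append(
                            {
                                **labels,
                                "model": model_kind,
                                "metric": metric,
                                "value": float("nan"),
                                "reason": f"model failure: {exc!r}",
                            }
                        )
        logger.info(
            "aim1 %s/%s target %.3g: %d replicates in %.1fs",
            scenario.cohort,
            scenario.dgm,
            target,
            scenario.replicates,
            time.monotonic() - t0,
        )
    tidy = pd.DataFrame(rows)
    keep = tidy["metric"].isin(scenario.metrics)
    return tidy[keep].reset_index(drop=True)


def run_aim2(
    scenario: Aim2Scenario,
    cohort: Cohort | None = None,
    frozen: FrozenDGM | None = None,
) -> pd.DataFrame:
    """Run the external-validation experiment; returns tidy results.

    One row per (target SE, replicate, metric ∈ {c_statistic, delong_se})
    with the frozen DGM's true C and prevalence carried along.
    """
    cohort, frozen = _prepare(scenario, cohort, frozen)
    if not np.isfinite(frozen.true_c):
        raise ValueError("frozen DGM has no usable true C (degenerate outcomes)")
    events = np.flatnonzero(frozen.y == 1)
    non_events = np.flatnonzero(frozen.y == 0)
    rows: list[dict] = []
    for s_idx, target_se in enumerate(scenario.target_ses):
        req = ValSampleSizeRequest(frozen.true_c, frozen.prevalence, target_se)
        result = n_val_for_c_precision(req)
        n_valid, n_events = result.n, result.n_events
        if n_events == 0:
            raise ValueError(f"scenario infeasible: zero events at target SE {target_se}")
        if n_valid >= len(cohort):
            raise ValueError(
                f"n_valid={n_valid} exceeds the full cohort (N={len(cohort)}); increase n_full"
            )
        if n_events > events.size or (n_valid - n_events) > non_events.size:
            raise ValueError("full cohort has too few events/non-events for the draw")
        for rep in range(scenario.replicates):
            rng = _replicate_seed(scenario.master_seed, s_idx, rep)
            take_e = rng.choice(events, size=n_events, replace=False)
            take_n = rng.choice(non_events, size=n_valid - n_events, replace=False)
            idx = np.concatenate([take_e, take_n])
            ms = evaluate_all(
                frozen.pi[idx], None, frozen.y[idx], metrics=("c_statistic", "delong_se")
            )
            rows.extend(
                ms.to_rows(
                    cohort=scenario.cohort,
                    dgm=scenario.dgm,
                    true_c=frozen.true_c,
                    prevalence=frozen.prevalence,
                    target_se=target_se,
                    n_valid=n_valid,
                    n_events=n_events,
                    replicate=rep,
                )
            )
    tidy = pd.DataFrame(rows)
    keep = tidy["metric"].isin(("c_statistic", "delong_se"))
    return tidy[keep].reset_index(drop=True)


def summarize(
    tidy: pd.DataFrame,
    by: Sequence[str] | None = None,
    scale_mape: bool = True,
) -> pd.DataFrame:
    """Aggregate tidy replicate rows into a table-shaped summary.

    Per group: median and 25th/75th percentiles (linear-interpolation
    convention) across non-missing replicates, the replicate mean, and
    missing counts.  MAPE values are additionally reported ×100 in a
    ``display`` column, matching the usual presentation.
    """
    if by is None:
        # n_valid varies per replicate in the development experiment, so it
        # is summarised, not grouped on, unless it is constant per target
        by = [
            c
            for c in ("cohort", "dgm", "model", "target_mape", "target_se", "n_dev", "metric")
            if c in tidy.columns
        ]
    records = []
    for key, grp in tidy.groupby(list(by), dropna=False, sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        ok = vals[np.isfinite(vals)]
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec["n_replicates"] = len(vals)
        rec["n_missing"] = int(len(vals) - len(ok))
        if len(ok) == 0:
            rec.update(median=float("nan"), q25=float("nan"), q75=float("nan"), mean=float("nan"))
            rec["all_missing"] = True
        else:
            rec.update(
                median=float(np.percentile(ok, 50)),
                q25=float(np.percentile(ok, 25)),
                q75=float(np.percentile(ok, 75)),
                mean=float(np.mean(ok)),
            )
            rec["all_missing"] = False
        if scale_mape and rec.get("metric") == "mape" and len(ok):
            rec["display"] = f"{100 * rec['median']:.2f} ({100 * rec['q25']:.2f}-{100 * rec['q75']:.2f})"
        records.append(rec)
    return pd.DataFrame(records)


def load_scenario(path: str) -> Aim1Scenario | Aim2Scenario:
    """Load a scenario from a YAML/JSON config file.

    The file must carry ``aim: 1`` or ``aim: 2`` plus any scenario fields;
    list-valued fields are converted to tuples.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    aim = cfg.pop("aim", None)
    if aim not in (1, 2):
        raise ValueError("config must set 'aim: 1' or 'aim: 2'")
    cls = Aim1Scenario if aim == 1 else Aim2Scenario
    for key, value in list(cfg.items()):
        if isinstance(value, list):
            cfg[key] = tuple(value)
    return cls(**cfg)


def run_manifest(scenario, started: float, path: str) -> None:
    """Write a small JSON manifest of a run (config, seed, timing)."""
    payload = {
        "scenario": asdict(scenario),
        "master_seed": scenario.master_seed,
        "elapsed_seconds": time.time() - started,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
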