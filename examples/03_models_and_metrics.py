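"""Fit the five analysis models and evaluate the full metric suite.

Each model exposes the same contract — a per-subject event-probability
prediction — but their probability semantics differ: the logistic models
and boosting produce strictly interior probabilities, while bagging and
random forests report vote proportions that can be exactly 0 or 1.
"""

import numpy as np

from predsize import evaluate_all, fit_model, freeze_dgm, make_cohort

cohort = make_cohort("minap", n=10_000, seed=3)
frozen = freeze_dgm("lr_main", cohort, seed=3)  # truth = fitted logistic surface

rng = np.random.default_rng(3)
dev_idx = rng.choice(len(cohort), size=1182, replace=True)  # recommended n_dev for MAPE 0.02
val_idx = np.setdiff1d(np.arange(len(cohort)), dev_idx)

X_dev, y_dev = cohort.X.iloc[dev_idx], frozen.y[dev_idx]
X_val, pi_val, y_val = cohort.X.iloc[val_idx], frozen.pi[val_idx], frozen.y[val_idx]

print(f"{'model':15s} {'MAPE':>7s} {'C':>7s} {'slope':>7s} {'CITL':>8s} {'Brier':>7s} {'p=0/1':>6s}")
for kind in ("lr_main", "lr_spline", "bagging", "random_forest", "boosting"):
    model = fit_model(kind, X_dev, y_dev, seed=11)
    ms = evaluate_all(model.predict(X_val), pi_val, y_val)
    print(
        f"{kind:15s} {ms.mape:7.4f} {ms.c_statistic:7.4f} {ms.cal_slope:7.3f} "
        f"{ms.citl:8.4f} {ms.brier:7.4f} {ms.n_excluded_boundary:6d}"
    )
# MAPE measures distance to the *true* probabilities; the last column
# counts boundary (0/1) predictions, which are excluded from the
# calibration measures and clipped for the C-statistic.  In this single
# replicate the matched logistic model sits at the 0.02 MAPE target
# (medians over many replicates land below it); the vote-proportion
# ensembles miss it by a factor of two or more.
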