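"""Run small versions of the two simulation experiments.

The development experiment repeatedly draws a development sample of the
formula-recommended size, fits each analysis model and evaluates it on
the never-drawn remainder of the cohort against the frozen truth.  The
validation experiment draws validation samples of the precision-formula
size and checks that the DeLong standard error of the C-statistic hits
its target.  Replicate counts here are kept small so the script runs in
about a minute; scale them up for stable medians.
"""

from predsize import Aim1Scenario, Aim2Scenario, freeze_dgm, make_cohort, run_aim1, run_aim2, summarize

cohort = make_cohort("minap", n=10_000, seed=5)
frozen = freeze_dgm("lr_main", cohort, seed=5)

dev = Aim1Scenario(
    dgm="lr_main",
    target_mapes=(0.02,),
    models=("lr_main", "random_forest", "boosting"),
    replicates=10,
    n_full=10_000,
    master_seed=5,
    metrics=("mape", "c_statistic", "cal_slope"),
)
summary = summarize(run_aim1(dev, cohort=cohort, frozen=frozen))
print("development experiment (target MAPE 0.02, n_dev = 1182):")
cols = ["model", "metric", "median", "q25", "q75"]
print(summary[cols].to_string(index=False))
# Median MAPE for the matched logistic model sits at or under the 0.02
# target; the random forest misses it by a wide margin.

val = Aim2Scenario(target_ses=(0.010, 0.025), replicates=50, n_full=10_000, master_seed=5)
vs = summarize(run_aim2(val, cohort=cohort, frozen=frozen))
print("\nvalidation experiment (mean DeLong SE vs target):")
print(vs[vs.metric == "delong_se"][["target_se", "mean"]].to_string(index=False))
# The achieved mean standard error tracks the requested target, which is
# what makes the precision formula usable for planning validation studies.
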