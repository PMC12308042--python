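"""Generate a calibrated synthetic cohort and inspect its properties.

The generator draws correlated mixed-type predictors through a Gaussian
copula and assigns each subject a true event probability from a logistic
truth surface whose intercept and coefficient scale are calibrated to a
target prevalence and expected C-statistic.
"""

from predsize import expected_c_of_probabilities, make_cohort

cohort = make_cohort("minap", n=20_000, seed=7)

print(f"subjects: {len(cohort)}")
print(f"predictors: {', '.join(cohort.schema.names)}")
print(f"expected prevalence (mean of true pi): {cohort.expected_prevalence:.4f}  (target 0.063)")
print(f"realised prevalence (mean of y):       {cohort.prevalence:.4f}")
print(f"expected C-statistic of true pi:       {expected_c_of_probabilities(cohort.pi):.4f}  (target 0.86)")
# The expected C is computed analytically from the true probabilities
# (no outcome noise), which is what the coefficient-scale calibration
# bisects on.

cohort.write("scratch_cohort.csv", "scratch_cohort.json")
print("wrote scratch_cohort.csv with columns y (outcome) and pi_true (true probability)")
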