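"""Sample-size calculation for developing and validating a risk model.

Development: how many subjects are needed so a logistic model with k
candidate parameters and outcome proportion p attains a target mean
absolute prediction error?  Validation: how many subjects are needed so
the estimated C-statistic has a target standard error?
"""

from predsize import (
    DevSampleSizeRequest,
    ValSampleSizeRequest,
    n_dev_for_mape,
    n_val_for_c_precision,
)

# An ACS-registry-like setting: in-hospital mortality at 6.3% prevalence,
# 10 candidate predictor parameters.
for target_mape in (0.02, 0.015, 0.01, 0.007, 0.005):
    r = n_dev_for_mape(DevSampleSizeRequest(prevalence=0.063, k=10, target_mape=target_mape))
    print(f"target MAPE {target_mape:5.3f}  ->  n_dev = {r.n:6d}  (events {r.n_events}, EPV {r.epv})")
# The n_dev column is the minimum development sample size; EPV is the
# implied events-per-variable, which drops well below the classical
# rule-of-ten for tight MAPE targets at low prevalence.

print()

# External validation of a model with anticipated C-statistic 0.862.
for se in (0.010, 0.025):
    r = n_val_for_c_precision(ValSampleSizeRequest(anticipated_c=0.862, prevalence=0.063, target_se=se))
    print(f"target SE(C) {se:5.3f}  ->  n_valid = {r.n:5d}  (events {r.n_events})")
# Halving the target standard error quadruples the validation sample
# size; higher anticipated C shrinks it.
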