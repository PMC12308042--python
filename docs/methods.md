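# Methods

This note records the models, conventions and numerical choices behind
`predsize`, and what the synthetic experiments do and do not show.

## Sample-size formulae

The development calculator targets the mean absolute prediction error
(MAPE) of a logistic prediction model: `n_dev` is the smallest integer
satisfying `n ≥ exp((−0.508 + 0.259 ln p + 0.504 ln k − ln MAPE)/0.544)`,
with `p` the anticipated outcome proportion (domain `0 < p ≤ 0.5`; code
the event as the minority class) and `k` the number of candidate
predictor parameters — spline basis columns each count as one. No
rounding rule is canonical for such formulae; we round up (ceiling),
which is the conservative choice and reproduces all published operating
points we use as fixtures. A target MAPE at or above `p` triggers a
warning rather than an error: the formula still evaluates, but such a
target is rarely meaningful relative to the prevalence.

The validation calculator targets the variance of the estimated
C-statistic under an approximately normal linear predictor:
`n_valid = (C − 2·T(Φ⁻¹(C), 1/√3) − C²) / (p(1−p)·SE²)`. The numerator
is strictly positive on `C ∈ (0.5, 1)`, equals 1/12 as `C → 0.5`
(because `arctan(1/√3) = π/6`) and vanishes as `C → 1`. The second Owen-T
argument `1/√3` is the value implied by the normal-linear-predictor
derivation; it is exposed as a module constant for override. Owen's T is
evaluated by adaptive quadrature on its defining integral with absolute
tolerance ~1e-10 — simpler to validate against an independent quadrature
than a series expansion, and far more accurate than the formula's inputs.
The standard normal quantile uses the double-precision inverse CDF;
accuracy is dominated by input rounding, not the quantile.

## Synthetic cohorts

Covariates are drawn through a Gaussian copula: latent N(0, R) vectors
mapped margin-by-margin to continuous (location/scale), binary
(quantile thresholding) and ordinal (cumulative-probability thresholds)
types. The two built-in configurations emulate the *structure* of large
cardiovascular registries — predictor counts and types, outcome
prevalence, discrimination, and (for the heart-failure-like cohort)
non-linear continuous effects — not their actual covariate
distributions, units, effect sizes or missingness, none of which are
public. Defaults are declared choices: standard normal continuous
margins, binary prevalences between 0.10 and 0.55, a 3-level ordinal,
and mild exchangeable latent correlation (0.2 within type, 0.1 across)
for realistic but benign collinearity.

Truth surfaces are logistic. The intercept is calibrated by root
bracketing so the mean true probability matches the target prevalence to
~1e-6; the non-intercept coefficients are then rescaled by bisection so
the *expected* C-statistic of the true probabilities — computed
analytically as the probability-weighted concordance over all pairs,
with no outcome-sampling noise — hits the target within 0.005, with the
intercept recalibrated at each step. The expected-C computation runs in
O(N log N) via sorted prefix sums over tie groups and is oracle-tested
against O(N²) enumeration. Non-linear effects in the heart-failure-like
surface come from a fixed menu (centred quadratic, saturating softplus,
piecewise-linear bend) on five of the nine continuous predictors, so a
4-df natural spline can capture them in principle.

Because the cohorts are synthetic and the truth surfaces logistic,
passing simulation tests demonstrates the *mechanics and qualitative
behaviour* of the sample-size formulae under controlled conditions; it
does not certify the formulae's numeric performance on any real
registry, where covariate distributions, effect strengths and
linear-predictor shapes differ.

## Data-generating mechanisms

A DGM freezes a probability rule over the full cohort: the chosen
analysis model is fitted to the cohort's base outcomes, its predictions
become the true probabilities π, and one outcome vector y ~ Bernoulli(π)
is simulated and frozen for all replicates (re-drawing outcomes per
replicate would conflate DGM noise with sampling noise). The frozen
true C and prevalence — computed from the full data with the frozen
outcomes — feed the validation formula. Tree DGMs yield vote-proportion
π containing exact 0s and 1s; Bernoulli simulation handles them exactly
and the true-C computation clips them only for ranking.

The neutral surface is constructed, not fitted: continuous predictors
are quintile-categorised (cuts at the 20/40/60/80th percentiles, values
equal to a cut going down), main-effect dummy coefficients inherit the
base surface's slope evaluated at per-category means, the ordinal enters
as dummies, and every cross-predictor pair of design columns receives an
interaction coefficient drawn N(0, τ²) with τ set so interactions carry
20% of linear-predictor variance; the intercept is then recalibrated to
the target prevalence. Fitting a ~250-parameter logistic model to one
synthetic outcome draw would mostly freeze noise, which is why
construction was preferred.

The natural cubic spline basis (used by the spline logistic model and
available to DGMs) is the standard truncated-power natural basis:
boundary knots at min/max, interior knots at the 25/50/75th percentiles,
df = 4 columns, linear beyond the boundary. It is tested by exact
recovery of natural cubic splines built independently and by vanishing
second differences on the extrapolation region.

## Analysis models

All five models expose one contract: predictor table in, event
probabilities out. Logistic fits are unpenalised maximum likelihood with
a weak-ridge refit (L2, C = 1e4) if the optimiser fails to converge —
the usual symptom of (quasi-)separation — logged when it happens.
Bagging is implemented as the all-features special case of the random
forest, which is its definition; both predict the *fraction of trees
whose leaf majority is the event class* (a leaf split exactly 50/50
contributes half a vote), so exact 0 and 1 predictions occur by design.
Boosting is stochastic gradient boosting with Bernoulli deviance,
initialised at the event log-odds; its additive log-odds ensemble keeps
predictions strictly interior.

Hyperparameters follow a freeze-before-simulating protocol: a grid
search scored by five-fold stratified cross-validated Brier score,
averaged over a small set of pre-simulation datasets, with ties broken
by a complexity proxy (fewer/shallower trees, larger shrinkage) since
training-time tie-breaks are hardware-dependent. Default grids: trees
{100, 250, 500}; forest subset {√p̃, p̃/3, p̃/2}; boosting depth {1,2,3}
× learning rate {0.01, 0.1} at subsample 0.5; bagging depth
unrestricted. When tuning is not run, frozen desk-scale defaults apply:
50 trees for bagging/forest, 100 for boosting at depth 2 and rate 0.1 —
half the full-scale tree counts, chosen once so a full simulation
scenario stays tractable on a single core.

## Metrics and boundary handling

MAPE is measured against the *true* probabilities and the Brier score
against outcomes, both on unmodified predictions. The C-statistic uses
midranks (ties count 1/2 — the convention consistent with the DeLong
estimator, and material when vote proportions tie heavily); its standard
error is DeLong's structural-components estimator, computed via midranks
in O(n log n) and oracle-tested against pairwise enumeration and against
the Monte-Carlo SD of the C-statistic. For vote-proportion models,
exact 0/1 predictions are clipped to [0.0001, 0.9999] for the
C-statistic only, and *excluded* from all calibration measures, with the
exclusion count reported.

Calibration-in-the-large is mean(y) − mean(π̂) (negative = systematic
overestimation). The calibration slope regresses the outcome on
logit(π̂) via a binomial GLM, with probabilities clamped to
[1e-6, 1−1e-6] after the exclusion rule; degenerate inputs (constant
logit, single class, fewer than 10 subjects) yield NaN with a recorded
reason rather than an exception, and such replicates are excluded from
medians with counts carried through.

ICI and E90 are the mean and 90th percentile of |ĉ(π̂) − π̂| where ĉ is
a locally weighted (lowess) regression of the outcome on π̂, span 0.75,
evaluated at each subject; an equal-frequency 20-bin mean curve is the
fallback when the smoother fails. Two numerical details matter: the
smoother runs with *zero* robustness iterations, because the default
iterations treat binary outcomes as outliers and bias the curve by
several points even on perfectly calibrated data; and a small `delta`
interpolation parameter keeps it near-linear-time on large validation
sets. A literal "probability-weighted |y − π̂|" variant is provided as a
secondary statistic (`ici_weighted`) for comparability, but the
smoothed-curve definition is primary.

## Simulation experiments

Development: per replicate, a development sample of size `n_dev` is
drawn *with replacement* from the full cohort (covariates + frozen
outcomes); the validation set is every subject never drawn — the literal
reading of "the remainder of the full data" under bootstrap-style
sampling, with expected size N(1−1/N)^{n_dev}. Each analysis model is
fitted to the draw and evaluated on the validation set against the
frozen truth. Validation experiment: a stratified sample with exactly
`n_events = round(n_valid·prevalence)` events is drawn per replicate and
the C-statistic of the frozen DGM predictions plus its DeLong SE are
recorded.

Replicate reproducibility comes from `numpy.random.SeedSequence` with a
(master seed, target index, replicate) spawn key: any replicate can be
regenerated in isolation, and a full run is byte-identical given the
same configuration. Summaries report the median and 25th/75th
percentiles (linear-interpolation convention — quartiles of a few
hundred replicates are convention-sensitive in the third decimal),
per-cell means, and missing-replicate counts; all-missing cells are
flagged, never dropped silently.

Desk-scale defaults — cohort N = 20,000, 100 development replicates, 200
validation replicates, halved tree counts — keep a full scenario in the
minutes range on one core; registry-scale runs (N ≈ 50,000, R = 1000)
are configuration changes, not code changes.

## Known limitations

- The expected-C calibration targets the analytic concordance of the
  true probabilities, so the *empirical* C of any single outcome draw
  wobbles around the target by sampling noise (~0.01 at N = 20,000).
- Registry realism is structural only (see above); effect sizes and
  correlations are declared, not estimated from data.
- The neutral surface's interaction-variance share (20%) is a single
  declared operating point, not a sweep.
- SMOTE/ROSE are not implemented; the provided minority-interpolation
  resampler is explicitly experimental and non-canonical.
- The validation engine evaluates the frozen DGM's own predictions (the
  external-validation framing); it does not revalidate freshly fitted
  models, which is the development engine's job.
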