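# Methods

## Outcome model

The 90-day modified Rankin Scale is modelled as a full 7-category
ordinal outcome with a cumulative-logit (proportional-odds) likelihood,
P(mRS ≤ k | x) = expit(α_k + xᵀβ). The orientation puts better outcomes
on the left, so a positive coefficient (odds ratio above 1) means a
better functional outcome. The proportional-odds assumption — one
common odds ratio per covariate across all six cumulative splits — is
taken as given, not tested; no partial-proportional-odds or
random-effects extensions are provided.

Fitting is maximum likelihood: BFGS on a monotone intercept
parameterization (α₀ free, subsequent intercepts spaced by positive
increments, which guarantees nondecreasing cumulative probabilities for
every patient), followed by Newton polishing in the natural (α, β)
space until the gradient's infinity norm falls below 1e−8; a fit is
rejected if it cannot reach 1e−6. Covariates are standardized
internally for conditioning and the estimates mapped back, so reported
coefficients are on each variable's own scale. Standard errors come
from the inverse observed information, evaluated by central differences
of the analytic gradient (step 1e−5, symmetrized). A standardized
coefficient exceeding 15 in absolute value triggers a
complete-separation warning and the fit is flagged rather than refused.
The fitter agrees with statsmodels' ordered logit to ~1e−9 on shared
problems and, on dichotomized outcomes, with binary logistic regression
to 1e−6; both checks are kept in the test suite as independent oracles.

## Design matrices

Model formulas are declarative term lists (linear, 3-knot restricted
cubic spline, reference-coded categorical, treatment indicator,
treatment×covariate product). The spline basis is the natural-spline
truncated-power construction with linearity enforced beyond the
boundary knots, normalized by the squared boundary span so spline
coefficients stay on the variable's scale. Knots default to the
10th/50th/90th percentiles of the training sample; variables with a
known inflection point have the middle knot forced there: brain
parenchymal fraction 80%, age 65 years, systolic blood pressure
130 mmHg, glucose 120 mg/dL. Knot count is fixed at three everywhere:
the effect summaries of interest are two-segment (below/above an
inflection), which a single interior knot expresses directly, and the
pooled sample sizes here do not support data-driven knot selection.
Volumes enter per 5 mL, onset-to-groin time per 30 min; occlusion
location is coded against the ICA/ICA-T reference and carotid
calcification subtype against "no calcification". Collateral score,
ASPECTS, NIHSS, and pre-stroke mRS enter linearly (each is summarized
by a single per-point odds ratio).

Effect summaries report exp(β) with 95% Wald intervals per linear or
dummy column; for spline terms, two odds ratios per unit are reported —
the chord slope of the fitted curve from the first knot to the
inflection point and from the inflection point to the last knot, with
delta-method standard errors.

## Variable selection and added value

Backward elimination refits the model repeatedly, removing at each step
the variable whose joint Wald test (all of its columns — spline or
dummy blocks as a unit) has the largest p-value above 0.20. Wald rather
than per-step likelihood-ratio tests is a deliberate choice: it is
cheaper and standard in this modelling tradition; the two agree closely
at these sample sizes. The treatment indicator, any variable
interacting with it, and an optional forced-in list (age and NIHSS in
the extended model) are never candidates. Added-value analyses use a
likelihood-ratio test (χ², df = added columns) at α = 0.05, followed —
only when fit improves — by a full cross-validated comparison of pooled
discrimination.

## Benefit prediction and matched-pair validation

Predicted benefit evaluates P(mRS 0–2) twice, with the treatment
indicator and all its interaction columns set to 1 and then 0, all else
fixed. Because individual counterfactuals are unobservable, observed
benefit is defined on 1:1 treated–control pairs: the good-outcome
indicator of the treated member minus the control member (−1, 0, +1),
paired with the mean of the two predicted benefits. Matching is greedy
nearest-neighbour without replacement on Mahalanobis distance over the
model's baseline covariates (standardized continuous + dummy-coded
categorical; covariance ridge-regularized at 1e−6), ties broken by a
seeded shuffle; matching on |predicted benefit difference| is available
as a sensitivity option. Matching is within trial by default, because
randomization guarantees exchangeability of arms only within a trial.
Greedy rather than optimal assignment is used: it is deterministic,
near-optimal for this diagnostic purpose, and dependency-free.

C-for-benefit is the concordance, over all pair-of-pair comparisons
with unequal observed benefit, of predicted with observed benefit
(strict inequality, ties at half credit — the same convention as the
outcome C-statistic). Mean benefit calibration is mean observed minus
mean predicted pair benefit; positive values mean the model
under-predicts benefit.

## Performance metrics

Concordance statistics (ordinal C, C for mRS 0–2, C-for-benefit) are
computed by a grouped rank algorithm: observations are grouped by
observed level (at most 7 levels), and for each level pair the
concordant/tied counts come from binary searches into the sorted scores
of the other group — O(L·n log n) overall, verified exactly against
O(n²) enumeration in the tests. The ranking score for the ordinal C is
the model's linear predictor, which is monotone in every predicted
exceedance probability under proportional odds. Standard errors are
leave-one-out jackknives computed in closed form from per-patient pair
sums (deterministic, no resampling) — these are the fold-level SEs that
feed the meta-analysis.

Calibration follows the logistic-recalibration convention: the slope is
the coefficient of logit(p̂) in a logistic regression of the observed
indicator; the intercept is estimated with logit(p̂) as a fixed offset
(slope held at 1). Predictions are clipped to [1e−6, 1−1e−6] before the
logit. Calibration curves use equal-count quantile bins with Wilson
binomial intervals; a degenerate (tied) binning is flagged rather than
hidden.

## Cross-validation, pooling, and comparison

Internal–external cross-validation leaves one trial out per fold: the
model is refitted on the remaining trials (spline knots re-resolved on
the training data), the held-out trial is predicted once, and all
requested metrics are computed on it. Variable selection, when used, is
performed once on the full development data before cross-validation;
folds re-estimate coefficients only (the formula, not the selection
path, is the model under test). Fold estimates are pooled with
DerSimonian–Laird random-effects meta-analysis on the natural metric
scale (pooled value, normal 95% CI, between-trial variance τ²); folds
on which a metric is undefined (e.g. a single-class trial) are dropped
from that metric's pooling with a warning, not imputed.

Delta C between two models is computed on the out-of-fold predictions
covering every patient exactly once, with a 500-resample bootstrap
percentile 95% CI; resampling is with replacement, stratified by trial
to preserve case-mix, and both models are recomputed on the same
resample. For delta C-for-benefit the resampling unit is the matched
pair. The point estimate is always contained in the reported interval
by construction.

Missing covariates are completed by chained equations (10 cycles):
linear-regression draws with coefficient-covariance perturbation and
residual noise for continuous variables (counts rounded and clipped to
their ranges), multinomial-logistic draws for categorical ones, with
the outcome and treatment arm always included as predictors. Five
completed datasets are the default. Metrics are combined across
imputations per fold by averaging values with Rubin-style total
variance (mean within-imputation variance plus (1 + 1/m) times the
between-imputation variance) before pooling across folds; model
comparisons use imputation-averaged predictions.

## Synthetic cohort generator

The generator emulates a pooled 7-trial randomized population of 1391
patients (trial sizes 394/248/55/155/162/326/51, ~1:1 allocation).
Covariate marginals target the published pooled baseline table: age
truncated-normal (67, 12.5) on [18, 95]; NIHSS rounded truncated-normal
(17, 5) on [2, 42]; systolic blood pressure truncated-normal (146, 25);
glucose and onset-to-groin log-normal (medians 122 mg/dL and 238 min);
ASPECTS, collateral, pre-stroke mRS, occlusion, and calcification
subtype categorical with the table's frequencies; white-matter-lesion
volume a 16% point mass at zero plus log-normal positives; old-infarct
volume a 76% zero mass plus log-normal positives; brain parenchymal
fraction truncated-normal (80.4, 2.8). Between-trial heterogeneity is
implemented purely as case-mix location shifts (±2 years of age and
similar), not as random coefficient effects — held-out-fold
heterogeneity in this design arises chiefly from case-mix and baseline
risk differences.

Outcomes are drawn from the proportional-odds process with generating
coefficients equal to the natural logs of the published common odds
ratios (imaging terms from the imaging model, age and NIHSS from its
clinical extension; old-infarct volume exactly null). Published
two-segment spline effects are translated into basis coefficients whose
fitted-curve chord slopes reproduce the printed below/above-inflection
ratios, using the same basis the design module builds — a correctly
specified working model can therefore recover the truth exactly. The
treatment×collateral interaction magnitude is never printed; the
default is ln(1.15) per collateral point (mild positive modification,
consistent with the term's inclusion in the source models) and is
overridable. Intercepts are calibrated by root-finding so that the
simulated control arm hits the published 27.9% good-outcome rate; the
remaining five cumulative cuts follow a plausible 7-category control
distribution logit-shifted to match, since only the mRS 0–2 proportions
per arm are published. Missingness is MCAR at a default 2% per
covariate (the source data had modest, unreported missingness);
outcome, arm, and trial label are never masked.

What the generator does *not* emulate: informative (MAR/MNAR)
missingness, measurement error in segmentation-derived volumes,
trial-specific inclusion rules, non-proportional or trial-varying
covariate effects, and correlation structure between covariates beyond
what the shifts induce (covariates are drawn independently within
trial). Passing tests therefore demonstrate the correctness of the
estimation and validation machinery under the stated generating
process, not the clinical performance of any model on real patients;
concordance and benefit metrics on this synthetic pool need not equal
the published values, which depend on real covariate correlations.

## Numerical choices and degenerate inputs

- Optimizer tolerances: BFGS gtol 1e−9, final gradient infinity norm
  below 1e−6 enforced, Newton polish target 1e−8.
- Probability clipping for calibration logits: 1e−6.
- Mahalanobis ridge: 1e−6 on the standardized-covariate correlation.
- Concordance with all observed values equal, calibration with constant
  predictions, and benefit metrics with fewer than two distinct
  observed pair benefits raise typed "undefined metric" errors instead
  of returning numbers.
- All stochastic steps (generation, imputation, matching tie-breaks,
  bootstrap) take explicit integer seeds; equal seed and input imply
  byte-identical output tables.

## Problem sizes used in the test suite

Simulation-based checks run at the smallest sizes that make their
tolerances meaningful: coefficient recovery averages five cohorts of
n = 10 000; Wald coverage uses 200 replicates of n = 2000; type-I-error
checks 500 replicates of n = 1000; calibration self-consistency one
cohort of n = 20 000; generator fidelity one draw of n = 50 000. These
are package choices made once, recorded here so the suite's claims are
interpretable.
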