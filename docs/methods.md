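# Methods

## Model

Measured postpartum blood loss `Y` (mL) given prepartum covariates `x`
(platelets G/L, hemoglobin g/L, fibrinogen g/L, FII %, FXIII %) is modelled
by a linear transformation model with standard-logistic inverse link:

    logit P(Y ≤ y | x) = h(y) + xᵀβ.

`h` is a monotone nondecreasing "baseline transformation" that plays the
role of cut-off-specific intercepts; `β` is a single coefficient vector
shared by every dichotomization of `Y`.  `exp(β_j)` is the odds ratio to
remain below *any* blood-loss volume per one-unit covariate increase.

**Sign convention.** OR > 1 means *less* bleeding.  Other software for
this model class writes the linear predictor as `h(y) − xᵀβ`; coefficients
from such implementations must be negated before comparison.

### Baseline transformation

`h` is a Bernstein polynomial of order `M` (default 6) on the observed
outcome range extended by 1% of the range per side, so every observation
is interior.  Nondecreasing coefficients `θ_0 ≤ … ≤ θ_M` guarantee
monotonicity; this is enforced by the smooth reparameterization
`θ_0 = γ_0`, `θ_k = θ_{k−1} + exp(γ_k)`.  Order 6 is flexible enough to
track a logit-scale empirical CDF of blood loss while keeping the
parameter count modest (12 parameters with the five covariates);
`order` is a constructor argument.  `h` is built on raw mL by default; a
`log_scale` flag builds it on log-mL instead, because the modelling scale
of the original analysis is not recorded.  Both scales give a valid
transformation model — the default is the raw scale, and the one
invariant worth remembering is that `β` is *not* comparable across the
two scales while the sign and the Wald z are essentially stable.

### Likelihood and optimization

The exact-continuous likelihood is used: each subject contributes
`log h'(y_i) + log λ(h(y_i) + x_iᵀβ)` with `λ` the standard-logistic
density.  Blood loss is recorded at round numbers; an interval-censored
refinement was considered and deliberately left out — with measurement
granularity of 10–50 mL against an outcome scale of thousands the
exact-continuous approximation is standard practice for this model class.

Optimization is quasi-Newton (L-BFGS, analytic gradients, gradient
tolerance 1e−8) over `(γ, β)` from 3 jittered starting points (seeded;
the base start solves a least-squares fit of the Bernstein basis to the
logit empirical CDF), followed by Newton polishing with a
finite-difference observed information until the gradient sup-norm falls
below tolerance.  Covariates are internally standardized for conditioning
(the platelet effect is ~2e−3 per G/L); coefficients, the baseline and
the covariance are mapped back to original units exactly, so
standardization is invisible in the reported scale.

Inference is Wald throughout: the covariance of `(θ̂, β̂)` is the inverse
observed information in `(γ, β)` mapped by the delta method.  A fit
reports `status = converged` only when the final gradient sup-norm is
below 1e−5 relative to the objective; non-convergence returns the fit
with a warning rather than raising.

### Derived quantities

- **Odds-ratio table**: `exp(β̂)` with level-`1−α` Wald CIs and two-sided
  p-values.
- **PPH prevalence curve**: `P(Y ≥ c | x) = 1 − σ(h(c) + xᵀβ̂)` over a grid
  of one focal covariate, others fixed at the cohort medians (the
  "reference subject").  The pointwise band applies the delta method to
  the linear predictor `η = h(c) + xᵀβ̂` (gradient `(b(c), x)` in
  `(θ, β)`) and maps through the response function, so it respects [0,1].
- **Shift effect** for a `Δ`-unit covariate shift: the odds factor
  `exp(Δβ̂)` (reported also as a percentage rise of the odds to stay below
  any cut-off) *and* the probability-scale drop
  `100·(1 − P₂/P₁)` of `P(Y ≥ 500 mL)` at the reference subject.  The two
  scales genuinely differ (≈ +10.5% odds vs ≈ −7% probability at the
  default design) and are never conflated; the PPH threshold defaults to
  500 mL and the shift to 50 G/L.

### Cut-off sweep

For each cut-off `c` in a grid (default: unique observed volumes between
the 5th and 95th MBL percentile), an ordinary binary logistic regression
of `1{Y ≤ c}` on the covariates is fitted by IRLS (relative deviance
change < 1e−10 or 50 iterations; covariance = inverse observed
information).  Cut-offs with fewer than 10 subjects on either side are
skipped and flagged.  Separation is detected when fitted probabilities
saturate beyond 1−1e−8 while the gradient has not vanished *or* the fit
classifies perfectly (under complete separation the gradient itself
underflows once the probabilities saturate, so the perfect-classification
check is required); such fits are returned with `converged = False`.  No
multiplicity adjustment is applied across cut-offs — the sweep is a
descriptive companion plot to the constant-coefficient model, not a
testing procedure.

### Association

Spearman correlation uses midranks for ties and the t approximation
`t = ρ√((n−2)/(1−ρ²))` on `n−2` df for the two-sided p-value, with a
seeded permutation alternative (default 10,000 shuffles) for
verification.  Pairs with a missing value are deleted pairwise and the
pair count used is reported.

## Synthetic cohorts

The generator emulates the study conditions: stratum sizes 677 / 409 /
223 (vaginal / elective cesarean / unplanned cesarean); per-stratum
marginals calibrated so median and IQR match the published cohort
description (gamma for the positive right-skewed labs — platelets,
fibrinogen, FII, FXIII — normal for hemoglobin); a Gaussian copula whose
platelet–FXIII entries are set via the exact bivariate-normal relation
`r = 2 sin(π ρ_s/6)` so the targeted Spearman correlations (0.228
prepartum, 0.293 postpartum) hold in expectation.  Copula entries not
pinned by a target default to 0 and are config-overridable — the true
joint dependence of the five covariates (and the within-subject pre/post
correlation) is not publicly recorded, and independence is the neutral
default for validating the fitting machinery.

Blood loss is drawn from the model itself: `Z ~ logistic`,
`Y = h⁻¹(Z − (x − x_ref)ᵀβ)` with `x_ref` the size-weighted stratum
medians, clamped to the support (clamp counts are warned).  The default
truth is `β_platelets = log(1.002)` per G/L, other coefficients 0, and
`h(y) = 3.3·log(y/400)` on [50, 6000] mL — a log-logistic baseline chosen
once so the simulated MBL marginal resembles the cohort (overall median
≈ 400 mL, right-skewed, range within the observed (100, 5700) mL).  One
global seed expands into independent streams (covariates, outcome,
per-replicate) via `numpy.random.SeedSequence.spawn`.

What the generator does *not* emulate: delivery-mode-specific blood-loss
distributions (a single `h` serves all strata, so the vaginal/cesarean
median split of the real cohort is not reproduced), clinical complication
covariates (atony, retained placenta, lacerations), informative
missingness, and any covariate dependence beyond the two targeted rank
correlations.  Passing recovery tests therefore demonstrates that the
estimator is consistent, approximately unbiased and correctly calibrated
*under the model*; they do not certify the model against real-data
misspecification.

## Validation harness

`recovery_study` repeats simulate → fit → record over seeded replicates
and reports per-coefficient mean, bias, empirical SE, bias SE and
CI-coverage proportion; non-convergent replicates are counted, not fatal.
The shipped acceptance run uses 200 replicates at the full study design
(n = 1309) — enough that the Monte-Carlo SE of the coverage estimate is
≈ 1.5 points — and a large-sample run at ≈ 19,600 subjects for the
consistency checks; these sizes are the package's validation design.

## Numerical notes and limitations

- Quantiles everywhere use linear interpolation between order statistics
  (the "type 7" rule); the convention used for the published summary
  table is unreported, so small discrepancies in IQRs are expected.
- Prediction at outcomes outside the fitted support clamps to the support
  endpoints with a warning; the CDF saturates there, consistent with a
  bounded-support model.  The implied density integrates to 1 only up to
  the boundary mass `σ(θ_0 + xᵀβ) + 1 − σ(θ_M + xᵀβ)` (≈ 1/n for a
  fitted model), which the validation checks account for.
- Complete-case analysis on outcome + mode + the five prepartum
  covariates; postpartum labs may be missing and only affect the
  postpartum correlation (pairwise deletion).  No imputation.
- Collinear designs are rejected with the offending columns named, never
  silently dropped.
- The delta-method band on the prevalence curve is pointwise, not
  simultaneous.
- Subgroup fits (vaginal, pooled cesarean) refit the full model —
  baseline and coefficients — per stratum; whether the original analysis
  shared the baseline across strata is unrecorded.  A flag separates the
  two cesarean strata instead of pooling.
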