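# Methods

## The disease model

Follow-up is measured on the age scale and the hazard is piecewise
constant over S age intervals (default seven: <50, 50–54, 55–59, 60–64,
65–69, 70–74, ≥75, with 60–64 the reference).  Splitting each subject's
follow-up into one record per occupied interval turns the survival
likelihood into a Poisson likelihood: the interval event indicator
d_ijk ∈ {0, 1} is treated as Poisson with mean

    ln μ_ijk = ln t_ijk + α_k + δ0_j + δ1_j·sex_ij
               + (X_ij − X̄_.j)·βW_j + (X̄_.j − X̄_..)·βB
               + (Z_ij − Z̄_.j)'γW + (Z̄_.j − Z̄_..)'γB ,

where t_ijk is the time at risk in interval k (entering as an offset),
α_k the log relative hazard of interval k (α_ref = 0), and X̄_.j, Z̄_.j
group means (center or center×sex).  Group-mean centering makes βW the
individual-level (within-center) association and βB the aggregate
(ecologic) one; γW is held constant across centers.  Center effects

    (u0_j, u1_j, uW_j) ~ MVN(0, Σ)

act on the intercept, the sex contrast, and the within-center exposure
slope.  The between-center outcome variance is σ0² in men and
σ0² + σ1² + 2σ01 in women, so a negative σ01 lets women's centers be
less heterogeneous than men's.  With a random slope, the intercept–slope
covariance is σW0 in men and σW0 + σW1 in women; dividing by the
corresponding standard deviations gives the correlations reported by
`derived_quantities`.

The conventional model ladder: (1) sex-specific random intercepts and
age effects only; (2) + individual-level covariates as overall values;
(3) individual covariates centered on group means plus the
between-center exposure contrast and aggregate covariates; (4) + the
random exposure slope.

### Person-period construction

Ages are continuous; interval membership is half-open [τ_{k−1}, τ_k), an
exit exactly on a boundary belongs to the earlier interval, and
zero-length rows are never emitted.  The first occupied interval gets
τ_k − age_entry (or the full spell when entry and exit share an
interval), the last gets age_exit − max(τ_{k−1}, age_entry), so total
person-time is conserved exactly — this, rather than any printed
shorthand, is what the counting-process definition requires.
Left-truncation is implicit: intervals before entry produce no rows.

## Estimation

The marginal likelihood integrates the center effects out of the
Poisson likelihood; the integral is approximated by Laplace's method,
which is accurate here because each center contributes hundreds of
person-periods.  Validation against 61-node adaptive Gauss–Hermite
quadrature on small random-intercept fixtures shows relative agreement
better than 1e-3, and in the degenerate limit Σ → 0 the criterion
reduces to the plain Poisson log-likelihood (checked to 1e-12).

The covariance is parameterized by its log-Cholesky factor (logs of the
diagonal, free off-diagonal), so any parameter vector maps to a valid
PSD matrix.  The outer optimizer (L-BFGS-B with finite-difference
gradients, relative tolerance 1e-8, gradient tolerance 1e-5, at most
500 iterations) moves only these q(q+1)/2 ≤ 6 parameters; for each
candidate Σ the fixed effects and all center modes are re-solved
exactly by a joint penalized Newton iteration (tolerance 1e-10, at most
100 steps, step-halving line search), warm-started from the previous
solve.  The objective is therefore the Laplace marginal log-likelihood
evaluated at the conditionally optimal fixed effects — the same nesting
lme4 uses for generalized linear mixed models.  Fixed effects are
initialized from the fixed-effects-only Poisson fit; variances start at
0.01, covariances at 0.  Diagonal log-Cholesky entries are bounded
below at log(1e-4), i.e. variance 1e-8, which is also the threshold for
reporting a boundary (zero-variance) solution.

Internally the person-period table is collapsed to one row per subject
(event flag, exit interval, occupancy time per interval): the Poisson
likelihood depends on the data only through these statistics, making
evaluations O(subjects) instead of O(rows).  When any model column
varies within a subject across intervals — e.g. the exposure ×
age-interval products of the proportional-hazards check — the collapse
silently switches to exact row-level units, which is the same
likelihood at higher cost.

Fixed-effect standard errors come from the inverse of the joint
(fixed + random-mode) negative Hessian at the optimum, i.e. they are
conditional on the estimated covariance, which is standard GLMM
practice.  Variance-component standard errors use a central-difference
Hessian of the profiled marginal likelihood over the covariance
parameters (profiling yields the correct Schur-complement curvature)
with delta-method transformation to the variance scale; they are
skipped at boundary solutions.  All intervals are Wald CIs on the log
scale.  Centers containing a single sex contribute no information on
the sex-contrast random effect beyond its prior; the Laplace mode
handles this without special-casing.

Design matrices are checked for rank by pivoted QR; collinear columns
(for example an aggregate covariate constant across all centers) are
dropped and logged.  Rows with missing model covariates are excluded
listwise at fit time with a logged count.

## Regression calibration

The questionnaire instrument Q carries center-specific systematic error
and random noise; a single reference recall R per subsampled subject is
assumed unbiased for true intake T but noisy.  In the subsample, R is
regressed by OLS on Q, the confounders, day-of-week and season
indicator contrasts, and center fixed effects; the fitted E(T | Q, Z)
replaces Q in the disease model.  Day-of-week and season exist only for
recall measurements, so cohort-wide predictions hold their indicators
at the subsample means — predictions are marginalized over the recall
day, and no subject's calibrated value depends on an undefined recall
date.  Each nutrient is regressed separately on its own questionnaire
value plus the shared covariates.  Episodically consumed exposures with
excess zeros (e.g. alcohol) are out of scope and should be passed
through uncalibrated.

Calibration uncertainty propagates by bootstrap: the calibration
subsample is resampled with replacement within center (preserving the
calibration design), the calibration model refitted, calibrated values
re-predicted, and the disease model refitted, B = 10 times by default.
Rubin's rule combines replicates: total variance = mean within-replicate
variance + (1 + 1/B) × between-replicate variance.  The reported point
estimate is the replicate mean; reporting the original-sample fit
instead is available by flag.  Replicates that fail to converge are
dropped with a warning; more than 20% dropped is an error.

## ICC diagnostics

`icc_continuous` fits a one-way random-intercept model by REML
(method-of-moments fallback); `icc_from_summary` works from published
per-group means and SDs: the between variance is the unweighted (or
weighted) *population* variance of the group means — no Bessel
correction, and the sampling variance of each mean is ignored, which is
negligible when groups hold thousands of subjects — and the within
variance is the mean squared SD.  On balanced raw data the two
method-of-moments routes agree to 1e-6 by construction.
`icc_binary` uses a random-intercept logistic model fitted by a small
Laplace approximation and reports the latent-scale ICC
σ_b²/(σ_b² + π²/3); a linear-probability decomposition is available by
flag, and effectively separated groups (latent ICC ≥ 0.95 or the
between-SD at its optimization cap) are flagged as boundary solutions.

## The synthetic cohort generator

The generator emulates a large European multicenter nutrition cohort
with a rare outcome: by default 28 centers × 1500 subjects, 70% women,
entry ages uniform on 35–70, administrative censoring 13 years after
entry (capped at age 80), baseline log hazard −7.0 per person-year at
the reference interval with a steep age gradient, sex rate ratio 0.66,
and exposure rate ratios 0.90 per 10 g/day at both the individual and
the aggregate level.  These defaults give roughly 400 events per
cohort, matching the order of a per-decade slice of a real multicenter
consortium, and random-effects variances 0.03 (intercept), 0.03 (sex)
and 0.003 (exposure slope) echoing variance components of published
multicenter analyses.  True intake is normal around normal center
means (between variance 4.5, within 18, ICC 0.2); the questionnaire is
Q = a_j + b_j·T + noise with center-specific a_j ~ N(4, 1.5²),
b_j ~ N(0.6, 0.1²) and noise variance 10 unless overridden; the recall
is R = T + noise with variance 50 (day-to-day dominated), observed on
an 8% subsample with uniform weekday and season labels.

Randomness is stream-seeded: the master seed spawns one substream per
center, each drawing in a fixed order (center effects, questionnaire
error parameters, center mean; then per-subject sex, entry age, intake,
questionnaire noise, subsample membership, recall noise, weekday,
season, event-time exponential), so adding centers or resizing a later
center never perturbs earlier centers' draws.  Event ages are drawn by
exact inversion of the piecewise-exponential cumulative hazard.

What the generator does *not* emulate: episodic (zero-inflated)
consumption, non-proportional hazards, competing risks, calendar-time
effects, or informative censoring.  Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to their violation.

## Simulation study designs used in the tests

Problem sizes are chosen so each Monte Carlo comparison has adequate
power at workstation scale:

- **Within/between recovery** — 20 cohorts at the generator defaults
  (28 × 1500, true RR 0.90 per 10 units, Σ = diag(0.03, 0.03, 0.003)),
  model (3) on true intake: the mean within-coefficient is compared to
  truth at 2 Monte Carlo SEs and the between-coefficient CI coverage to
  90%.
- **Reported-SE calibration** — the spread/reported-SE comparison uses
  cohorts *without* slope heterogeneity (Σ = diag(0.03, 0.03, 0)),
  because with an unmodelled random slope the across-seed spread of the
  within coefficient includes realized slope heterogeneity that the
  conditional SE is not meant to cover (with it, the ratio is ≈ 1.4;
  under the matched model it is ≈ 1.0).
- **Measurement-error study** — questionnaire slope fixed at 0.6,
  questionnaire noise variance 20, unbiased recalls on the 8%
  subsample, no slope heterogeneity, 16 centers × 800 subjects,
  baseline log hazard −4.5 and a strong protective exposure (RR 0.5 per
  10 units): with these conditions the attenuation bias (≈ 60% of the
  effect) dominates the per-seed Monte Carlo noise, so the calibrated
  estimate is closer to truth than the naive one in ≈ 19/20 seeds,
  while the Rubin-combined SE exceeds the single-fit SE.  With a weak
  effect (RR 0.90) the same comparison is swamped by noise at any
  desk-scale cohort size; de-attenuation is a multiplicative
  correction, so a larger effect changes the detectability, not the
  phenomenon.
- **Intercept–slope correlation** — 5 cohorts of 30 centers × 300 with
  strong heterogeneity (σ0² = 0.2, σW² = 0.004, corr 0.3) and a common
  outcome; per-seed correlation estimates are intrinsically noisy at 30
  centers (SD ≈ 0.27), which the 2-MC-SE criterion reflects honestly.

## Numerical choices and degenerate inputs

Zero hazards (log hazard −∞) are valid and produce censored records.
A questionnaire column with no between-group variation warns rather
than errors; its between column is all zeros and the rank check removes
it from the design if redundant.  Negative method-of-moments between
variances truncate to zero.  Correlations with a zero-variance
denominator are reported missing.  Ties at interval boundaries resolve
to the earlier interval.  The boundary detection threshold for variance
components is 1e-8 on the variance scale.

## Known limitations

- The Laplace approximation can be optimistic for centers with very few
  events; the quadrature cross-check covers small fixtures, not every
  regime.
- Variance-component SEs are Wald/delta-method quantities; profile or
  bootstrap intervals for variances are out of scope.
- The bootstrap resamples the calibration subsample only; cohort-level
  resampling of the disease model is a non-goal.
- Calibration assumes a linear measurement-error model with
  homoscedastic errors and a single reference replicate per subject;
  episodically consumed foods are excluded.
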