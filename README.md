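# pwemix

Multilevel piecewise-exponential proportional-hazards modelling for
multicenter cohort studies.

In a multicenter cohort (say, a European nutrition consortium with
recruitment centers across ten countries), the association between an
exposure and disease risk can be read at two levels: the
**within-center** (individual) association — how a subject's deviation
from their center's mean exposure relates to their hazard — and the
**between-center** (aggregate, ecologic) association — how center mean
exposures track center incidence.  `pwemix` estimates both at once,
with center-level random effects quantifying residual heterogeneity,
and corrects the individual-level exposure for measurement error by
regression calibration against a reference instrument.

## The model

Age is the time scale and the hazard is piecewise constant over S age
intervals, which makes the survival likelihood a Poisson likelihood on
the person-period table: one row per subject × occupied interval,
event indicator `d`, time at risk `t` as a log offset.  The disease
model is

    ln μ_ijk = ln t_ijk + α_k + δ0_j + δ1_j·sex_ij
               + (X_ij − X̄_.j)·βW + (X̄_.j − X̄_..)·βB
               + (Z_ij − Z̄_.j)'γW + (Z̄_.j − Z̄_..)'γB

with center effects (u0_j, u1_j, uW_j) ~ MVN(0, Σ) on the intercept,
the sex contrast and (optionally) the within-center exposure slope.
Group-mean centering makes βW and βB separately interpretable;
Σ's diagonal measures between-center heterogeneity in incidence and in
the association itself.  Estimation maximizes a Laplace-approximated
marginal likelihood with the covariance held positive semi-definite by
a log-Cholesky parameterization; the approximation is validated in the
test suite against 61-node adaptive Gauss–Hermite quadrature and
against direct survival-likelihood maximization.  See
`docs/methods.md` for the full account.

An error-prone questionnaire exposure Q can be replaced by the
regression-calibration prediction E(T | Q, Z) fitted on a subsample
carrying an unbiased reference measurement (e.g. a single standardized
24-hour dietary recall); calibration uncertainty is propagated by
resampling the subsample and combining replicate fits with Rubin's
rule.  Intraclass correlations (from raw data or from published
center-level summary tables) quantify how much exposure variation sits
at the center level.

## Worked example

Simulate a 20-center cohort whose questionnaire has center-specific
systematic error (slope 0.6) around a true intake with rate ratio 0.70
per 10 g/day, then compare the questionnaire-based and calibrated fits:

```python
import numpy as np
from pwemix import (SimulationConfig, simulate_cohort, fit_level, predict_rr,
                    fit_calibration, predict_expected_intake, icc_continuous)

config = SimulationConfig(n_centers=20, subjects_per_center=1000,
                          baseline_log_hazard=-5.0,
                          beta_within=np.log(0.7) / 10, beta_between=np.log(0.7) / 10,
                          random_effects_cov=np.diag([0.03, 0.03, 0.0]),
                          questionnaire_slopes=0.6, seed=1)
cohort = simulate_cohort(config)
print(f"cohort: {len(cohort)} subjects, {cohort['event'].sum()} events, "
      f"{cohort['recall'].notna().sum()} recall measurements")

icc = icc_continuous(cohort["exposure_q"], cohort["center_id"])
print(f"questionnaire intake ICC: {icc.icc:.2f}")

naive = fit_level(cohort, 3, exposure="exposure_q")
rr = predict_rr(naive, "exposure_q__within", increment=10.0)
print(f"questionnaire within-center RR per 10 g/day: "
      f"{rr.rr:.2f} ({rr.ci_low:.2f}, {rr.ci_high:.2f})")

cal_model = fit_calibration(cohort)
cohort = cohort.assign(exposure_q__cal=predict_expected_intake(cal_model, cohort))
cal = fit_level(cohort, 3, exposure="exposure_q__cal")
rr_c = predict_rr(cal, "exposure_q__cal__within", increment=10.0)
rr_b = predict_rr(cal, "exposure_q__cal__between", increment=10.0)
print(f"calibration slope: {cal_model.slope:.2f} (n={cal_model.n})")
print(f"calibrated within-center  RR per 10 g/day: "
      f"{rr_c.rr:.2f} ({rr_c.ci_low:.2f}, {rr_c.ci_high:.2f})")
print(f"calibrated between-center RR per 10 g/day: "
      f"{rr_b.rr:.2f} ({rr_b.ci_low:.2f}, {rr_b.ci_high:.2f})")

from pwemix import derived_quantities
dq = derived_quantities(cal)
print(f"outcome variance across centers: men {dq['var_men']:.3f} "
      f"(SE {dq['se_var_men']:.3f}), women {dq['var_women']:.3f}")
```

Output:

```
cohort: 20000 subjects, 1170 events, 1628 recall measurements
questionnaire intake ICC: 0.21
questionnaire within-center RR per 10 g/day: 0.77 (0.67, 0.88)
calibration slope: 0.72 (n=1628)
calibrated within-center  RR per 10 g/day: 0.69 (0.57, 0.84)
calibrated between-center RR per 10 g/day: 0.64 (0.43, 0.96)
outcome variance across centers: men 0.035 (SE 0.025), women 0.062
```

Reading it: about a fifth of questionnaire variance sits between
centers (ICC 0.21).  The questionnaire-based within-center rate ratio
(0.77) is attenuated toward the null by measurement error; calibration
recovers the generating value (0.69 vs. truth 0.70) at the price of a
wider interval, and the between-center estimate points the same way
with much less information behind it (20 centers vs. 20 000 subjects).
The variance components say how much log-incidence heterogeneity
remains across centers after adjustment, separately for men and women
(women combine the intercept and sex-contrast random effects).

A command-line interface mirrors the library:

```sh
pwemix pipeline --config examples/pipeline_demo.yaml --out results/demo
```

runs simulate → expand → fit models (1)–(4) → calibrate → bootstrap →
Rubin-combine and writes coefficient tables plus a reproducibility
manifest.

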