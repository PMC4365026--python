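"""The multilevel Poisson disease model: likelihood correctness against
independent oracles, recovery of generating parameters, and reporting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pwemix import (AgeGrid, ModelSpec, SimulationConfig, compare_variance_components,
                    derived_quantities, expand, fit, fit_level, marginal_loglik,
                    predict_rr, simulate_cohort)
from pwemix.glmm import FitResult, _Collapsed

from _oracles import agh_random_intercept_loglik


def _params_for(pp, spec, grid, alpha_free, beta, theta=()):
    return np.concatenate([alpha_free, beta, theta])


class TestMarginalLoglik:
    def test_matches_adaptive_quadrature(self, tiny_ri_fixture, grid):
        _, pp = tiny_ri_fixture
        spec = ModelSpec(fixed_terms=("exposure_q",), random_sex_slope=False)
        ai = [k for k in sorted(pp["interval"].unique()) if k != grid.reference_interval]
        rng = np.random.default_rng(0)
        alpha_free = rng.normal(0, 0.3, len(ai))
        beta = np.array([-3.2, -0.3, 0.01])
        for sd in (0.15, 0.4, 0.8):
            theta = np.array([np.log(sd)])
            lap = marginal_loglik(_params_for(pp, spec, grid, alpha_free, beta, theta),
                                  pp, spec, grid)
            agh = agh_random_intercept_loglik(pp, grid, alpha_free, beta,
                                              ["exposure_q"], sd ** 2)
            assert lap == pytest.approx(agh, rel=1e-3)

    def test_degenerate_prior_equals_fixed_effects_poisson(self, tiny_ri_fixture, grid):
        _, pp = tiny_ri_fixture
        spec = ModelSpec(fixed_terms=("exposure_q",), random_sex_slope=False)
        spec_fe = ModelSpec(fixed_terms=("exposure_q",), random_intercept=False,
                            random_sex_slope=False)
        ai = [k for k in sorted(pp["interval"].unique()) if k != grid.reference_interval]
        alpha_free = np.zeros(len(ai))
        beta = np.array([-3.0, -0.2, 0.02])
        lap = marginal_loglik(np.concatenate([alpha_free, beta, [np.log(1e-6)]]),
                              pp, spec, grid)
        fe = marginal_loglik(np.concatenate([alpha_free, beta]), pp, spec_fe, grid)
        assert lap == pytest.approx(fe, abs=1e-4)

    def test_wrong_parameter_length_rejected(self, tiny_ri_fixture, grid):
        _, pp = tiny_ri_fixture
        spec = ModelSpec(fixed_terms=("exposure_q",), random_sex_slope=False)
        with pytest.raises(ValueError, match="length"):
            marginal_loglik(np.zeros(3), pp, spec, grid)


class TestFit:
    @staticmethod
    def _glm_oracle(pp):
        X = pd.get_dummies(pp["interval"].astype("category"), prefix="age",
                           dtype=float).drop(columns=["age_3"])
        X["intercept"] = 1.0
        X["sex"] = pp["sex"]
        X["exposure_q"] = pp["exposure_q"]
        return sm.GLM(pp["d"], X, family=sm.families.Poisson(),
                      offset=np.log(pp["t"])).fit()

    def test_fixed_effects_path_matches_irls_oracle(self, grid):
        cfg = SimulationConfig(n_centers=6, subjects_per_center=400,
                               baseline_log_hazard=-4.6,
                               random_effects_cov=np.zeros((3, 3)), seed=3)
        pp = expand(simulate_cohort(cfg), grid)
        spec = ModelSpec(fixed_terms=("exposure_q",), random_intercept=False,
                         random_sex_slope=False)
        res = fit(pp, spec, grid)
        glm = self._glm_oracle(pp)
        for term in ("intercept", "sex", "exposure_q"):
            assert res.beta[term] == pytest.approx(glm.params[term], abs=1e-6)
            assert res.se_beta[term] == pytest.approx(glm.bse[term], rel=1e-6)

    def test_zero_sigma_data_shrinks_to_poisson(self, grid):
        # with many centers and no true heterogeneity the fitted variance
        # components concentrate near zero and the mixed fit approaches
        # the plain Poisson solution (slope coefficients fastest)
        cfg = SimulationConfig(n_centers=30, subjects_per_center=400,
                               baseline_log_hazard=-4.6,
                               random_effects_cov=np.zeros((3, 3)), seed=3)
        pp = expand(simulate_cohort(cfg), grid)
        res = fit(pp, ModelSpec(fixed_terms=("exposure_q",)), grid,
                  compute_vc_se=False)
        glm = self._glm_oracle(pp)
        assert res.vc["sigma2_intercept"] < 0.01
        assert res.beta["exposure_q"] == pytest.approx(glm.params["exposure_q"], abs=1e-4)
        assert res.beta["sex"] == pytest.approx(glm.params["sex"], abs=1e-4)
        assert res.beta["intercept"] == pytest.approx(glm.params["intercept"], abs=1e-3)

    def test_loglik_reproducible_from_stored_params(self, grid):
        cfg = SimulationConfig(n_centers=5, subjects_per_center=300,
                               baseline_log_hazard=-4.2, seed=15)
        pp = expand(simulate_cohort(cfg), grid)
        spec = ModelSpec(fixed_terms=("exposure_q",))
        res = fit(pp, spec, grid, compute_vc_se=False)
        again = marginal_loglik(res.params, pp, spec, grid)
        assert again == pytest.approx(res.loglik, abs=1e-8)

    def test_outer_iterations_ascend(self, grid):
        cfg = SimulationConfig(n_centers=6, subjects_per_center=300,
                               baseline_log_hazard=-4.2, seed=19)
        pp = expand(simulate_cohort(cfg), grid)
        res = fit(pp, ModelSpec(fixed_terms=("exposure_q",)), grid,
                  compute_vc_se=False)
        trace = np.array(res.outer_trace)
        assert len(trace) >= 1
        assert np.all(np.diff(trace) >= -1e-6)

    def test_offset_doubling_shifts_intercept_by_log_two(self, grid):
        cfg = SimulationConfig(n_centers=4, subjects_per_center=300,
                               baseline_log_hazard=-4.5,
                               random_effects_cov=np.zeros((3, 3)), seed=23)
        pp = expand(simulate_cohort(cfg), grid)
        spec = ModelSpec(fixed_terms=("exposure_q",), random_intercept=False,
                         random_sex_slope=False)
        res = fit(pp, spec, grid)
        pp2 = pp.assign(t=2.0 * pp["t"])
        res2 = fit(pp2, spec, grid)
        assert res2.beta["intercept"] == pytest.approx(res.beta["intercept"] - np.log(2),
                                                       abs=1e-6)
        assert res2.beta["exposure_q"] == pytest.approx(res.beta["exposure_q"], abs=1e-6)
        # the offset constant d*ln2 and the intercept shift cancel exactly,
        # so the maximized log-likelihood is invariant
        assert res2.loglik == pytest.approx(res.loglik, abs=1e-5)

    def test_nested_models_order_loglik(self, grid):
        cfg = SimulationConfig(n_centers=6, subjects_per_center=250,
                               baseline_log_hazard=-4.0, seed=31)
        cohort = simulate_cohort(cfg)
        fits = {lv: fit_level(cohort, lv, exposure="exposure_q",
                              compute_vc_se=False) for lv in (1, 2, 3, 4)}
        assert fits[2].loglik >= fits[1].loglik - 1e-6
        assert fits[4].loglik >= fits[3].loglik - 1e-6

    def test_exposure_shift_invariance_after_centering(self, grid):
        cfg = SimulationConfig(n_centers=5, subjects_per_center=300,
                               baseline_log_hazard=-4.2, seed=37)
        cohort = simulate_cohort(cfg)
        a = fit_level(cohort, 3, exposure="exposure_q", compute_vc_se=False)
        shifted = cohort.assign(exposure_q=cohort["exposure_q"] + 100.0)
        b = fit_level(shifted, 3, exposure="exposure_q", compute_vc_se=False)
        assert b.beta["exposure_q__within"] == pytest.approx(
            a.beta["exposure_q__within"], abs=1e-6)
        assert b.beta["exposure_q__between"] == pytest.approx(
            a.beta["exposure_q__between"], abs=1e-6)

    def test_reported_se_calibrated_under_matched_model(self):
        """Across repeated cohorts generated without slope heterogeneity
        (so the level-3 model is correctly specified), the across-seed
        spread of the within coefficient matches its reported SE."""
        bw, sew = [], []
        for seed in range(24):
            cfg = SimulationConfig(subjects_per_center=400,
                                   random_effects_cov=np.diag([0.03, 0.03, 0.0]),
                                   seed=800 + seed)
            cohort = simulate_cohort(cfg)
            f = fit_level(cohort, 3, exposure="true_intake", compute_vc_se=False)
            bw.append(f.beta["true_intake__within"])
            sew.append(f.se_beta["true_intake__within"])
        ratio = np.std(bw, ddof=1) / np.mean(sew)
        assert 0.75 <= ratio <= 1.25

    def test_single_sex_centers_estimable(self, grid):
        # women-only centers contribute no information on the sex-contrast
        # random effect beyond the prior; the fit must stay finite
        cfg = SimulationConfig(n_centers=6, subjects_per_center=250,
                               baseline_log_hazard=-4.0,
                               sex_fraction=[1.0, 1.0, 0.5, 0.5, 0.0, 0.7],
                               seed=41)
        cohort = simulate_cohort(cfg)
        res = fit_level(cohort, 2, exposure="exposure_q", compute_vc_se=False,
                        centering="center")
        assert res.converged
        assert np.isfinite(res.beta).all()
        assert np.isfinite(res.posterior_modes[["u_intercept", "u_sex"]]).to_numpy().all()


class TestReporting:
    def _dummy_fit(self, Sigma, names):
        L = np.linalg.cholesky(Sigma)
        theta = []
        for i in range(len(names)):
            for j in range(i + 1):
                theta.append(np.log(L[i, i]) if i == j else L[i, j])
        spec = ModelSpec(random_sex_slope="sex" in names,
                         random_exposure_slope="exposure" in names,
                         exposure_within="x__within" if "exposure" in names else None)
        return FitResult(
            spec=spec, grid=AgeGrid(), alpha=pd.Series(dtype=float),
            beta=pd.Series({"x": -0.0105360516}), se_alpha=pd.Series(dtype=float),
            se_beta=pd.Series({"x": 0.003}), vc={}, vc_se={},
            theta=np.array(theta), cov_theta=None, loglik=0.0, converged=True,
            boundary=False, n_iter=1, posterior_modes=pd.DataFrame(),
            n_rows=0, n_events=0, dropped_columns=[])

    def test_rate_ratio_examples(self):
        f = self._dummy_fit(np.eye(2) * 0.01, ("intercept", "sex"))
        rr10 = predict_rr(f, "x", 10.0)
        assert rr10.rr == pytest.approx(0.90, abs=5e-4)
        rr20 = predict_rr(f, "x", 20.0)
        assert rr20.rr == pytest.approx(rr10.rr ** 2, rel=1e-12)
        f.beta["x"] = 0.0
        rr = predict_rr(f, "x", 10.0)
        assert rr.rr == 1.0
        assert rr.ci_low * rr.ci_high == pytest.approx(1.0, rel=1e-12)
        with pytest.raises(KeyError):
            predict_rr(f, "unknown", 1.0)

    def test_sex_specific_outcome_variances(self):
        Sigma = np.array([[0.04, -0.01], [-0.01, 0.01]])
        f = self._dummy_fit(Sigma, ("intercept", "sex"))
        dq = derived_quantities(f)
        assert dq["var_men"] == pytest.approx(0.04)
        assert dq["var_women"] == pytest.approx(0.03)

    def test_women_variance_zero_at_perfect_negative_correlation(self):
        # sigma01 = -sigma0*sigma1 with sigma0 = sigma1 collapses the
        # women's variance sigma0^2 + sigma1^2 + 2*sigma01 to zero
        Sigma = np.array([[0.04, -0.04], [-0.04, 0.04]]) + 1e-12 * np.eye(2)
        f = self._dummy_fit(Sigma, ("intercept", "sex"))
        dq = derived_quantities(f)
        assert dq["var_women"] == pytest.approx(0.0, abs=1e-9)

    def test_intercept_slope_correlation_recovered(self):
        """Random-slope model recovers a generating intercept-slope
        correlation of 0.3 (men) within 2 Monte Carlo SEs over seeds."""
        rho, s0, sw = 0.3, 0.2, 0.004
        Sig = np.array([[s0, 0.0, rho * np.sqrt(s0 * sw)],
                        [0.0, 0.05, 0.0],
                        [rho * np.sqrt(s0 * sw), 0.0, sw]])
        ests = []
        for seed in range(5):
            cfg = SimulationConfig(n_centers=30, subjects_per_center=300,
                                   baseline_log_hazard=-3.8,
                                   random_effects_cov=Sig, seed=700 + seed)
            cohort = simulate_cohort(cfg)
            f = fit_level(cohort, 4, exposure="true_intake", centering="center",
                          compute_vc_se=False)
            ests.append(derived_quantities(f)["corr_intercept_slope_men"])
        ests = np.array(ests)
        mcse = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - rho) < 2 * mcse

    def test_variance_component_percent_change(self):
        a = {"sigma2_intercept": 0.04, "sigma2_sex": 0.0}
        b = {"sigma2_intercept": 0.04, "sigma2_sex": 0.01}
        out = compare_variance_components(a, b)
        assert out["sigma2_intercept"] == 0.0
        assert out["sigma2_sex"] is None  # undefined when the base VC is 0

    def test_coefficient_table_levels(self, grid):
        cfg = SimulationConfig(n_centers=4, subjects_per_center=200,
                               baseline_log_hazard=-4.0, seed=51)
        cohort = simulate_cohort(cfg)
        res = fit_level(cohort, 3, exposure="exposure_q", compute_vc_se=False)
        table = res.coefficient_table()
        lv = dict(zip(table["term"], table["level"]))
        assert lv["exposure_q__within"] == "individual"
        assert lv["exposure_q__between"] == "aggregate"
        assert any(t.startswith("age[") for t in table["term"])
        assert any(t.startswith("vc[") for t in table["term"])


class TestCollapse:
    def test_row_level_fallback_for_interval_varying_columns(self, grid):
        cfg = SimulationConfig(n_centers=3, subjects_per_center=100,
                               baseline_log_hazard=-4.0, seed=61)
        pp = expand(simulate_cohort(cfg), grid)
        spec = ModelSpec(fixed_terms=("exposure_q",), random_sex_slope=False)
        subj = _Collapsed(pp, spec, grid)
        assert subj.n < len(pp)  # collapsed to subjects
        pp2 = pp.assign(tv=pp["interval"].astype(float))  # interval-varying
        spec2 = ModelSpec(fixed_terms=("exposure_q", "tv"), random_sex_slope=False)
        rows = _Collapsed(pp2, spec2, grid)
        assert rows.n == len(pp2)  # exact row-level representation

    def test_positive_offsets_required(self, grid, dense_pp):
        bad = dense_pp.copy()
        bad.loc[bad.index[0], "t"] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            _Collapsed(bad, ModelSpec(), grid)
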