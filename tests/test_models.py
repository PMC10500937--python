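"""Mixed-model estimators: degenerate-case oracles, predictions, validation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from iculos import (ModelSpec, fit_glmm_log_gaussian, fit_lmm, generate_registry,
                    normality_check, predict_los, r_squared,
                    residual_diagnostics, simple_sim_config,
                    split_sample_validation)
from iculos.models import split_sample_validation as ssv
from iculos.registry import build_design, linear_predictor
from conftest import SMALL_BETA, SMALL_TERMS, registry_from_los


def single_site_registry(n=60, seed=0):
    rng = np.random.default_rng(seed)
    reg = registry_from_los({1: np.round(rng.lognormal(0.6, 1.0, n), 4)})
    return reg


class TestLmm:
    def test_single_site_intercept_only_is_ols_mean(self):
        reg = single_site_registry()
        m = fit_lmm(reg, ModelSpec(fixed_terms=[], interactions=[]))
        assert m.tau2_hat == 0.0
        assert m.beta_hat["intercept"] == pytest.approx(
            np.log(reg.patients["los_days"]).mean(), abs=1e-10)

    def test_noise_free_recovery(self, small_spec):
        # log LOS = x'beta exactly => beta recovered, residual variance ~ 0
        cfg = simple_sim_config(5, 200, beta=SMALL_BETA, gen_terms=SMALL_TERMS,
                                tau2=0.0, sigma2=1.0, seed=2)
        reg = generate_registry(cfg)
        spec = small_spec
        X, names, _ = build_design(reg.patients, spec)
        eta = linear_predictor(reg.patients, spec,
                               {k: v for k, v in SMALL_BETA.items()})
        reg.patients["los_days"] = np.exp(eta)
        m = fit_lmm(reg, spec)
        truth = np.array([SMALL_BETA[n] for n in names])
        assert np.allclose(m.beta_hat.to_numpy(), truth, atol=1e-6)
        assert m.sigma2_hat < 1e-10

    def test_information_criteria_identities(self, lmm20):
        p = len(lmm20.beta_hat) + 2
        assert lmm20.aic == pytest.approx(-2 * lmm20.loglik + 2 * p)
        assert lmm20.bic == pytest.approx(
            -2 * lmm20.loglik + p * math.log(lmm20.n_used))

    def test_blup_shrinkage(self, lmm20, registry20, small_spec):
        # every predicted intercept is shrunk toward zero relative to the
        # site's raw mean residual deviation
        X, _, mask = build_design(registry20.patients, small_spec)
        resid = (np.log(registry20.patients.loc[mask, "los_days"])
                 - X @ lmm20.beta_hat.to_numpy())
        raw = resid.groupby(registry20.patients.loc[mask, "icu_id"]).mean()
        re = lmm20.re.set_index("icu_id")["re"]
        assert (re.abs() <= raw.abs().reindex(re.index) + 1e-12).all()
        assert abs(re.mean()) < 0.05

    def test_non_positive_los_rejected(self, small_spec):
        reg = registry_from_los({1: [1.0, 2.0], 2: [3.0, 0.0]})
        with pytest.raises(ValueError):
            fit_lmm(reg, small_spec)


class TestGlmm:
    def test_single_site_intercept_only_is_arithmetic_mean(self):
        # minimizing sum (y - exp(b))^2 forces exp(b) = mean(y)
        reg = single_site_registry(seed=1)
        m = fit_glmm_log_gaussian(reg, ModelSpec(fixed_terms=[], interactions=[]))
        assert math.exp(m.beta_hat["intercept"]) == pytest.approx(
            reg.patients["los_days"].mean(), rel=1e-8)
        assert m.tau2_hat == 0.0

    def test_matches_independent_nls_oracle(self, small_spec):
        # tau2 pinned at zero: the fit must agree with scipy's own
        # Levenberg-Marquardt NLS of y = exp(x'b) + e
        cfg = simple_sim_config(2, 250, beta=SMALL_BETA, gen_terms=SMALL_TERMS,
                                tau2=0.0, sigma2=0.6, seed=11)
        reg = generate_registry(cfg)
        m = fit_glmm_log_gaussian(reg, small_spec, fix_tau2_zero=True)
        X, names, _ = build_design(reg.patients, small_spec)
        y = reg.patients["los_days"].to_numpy()
        nls = least_squares(lambda b: y - np.exp(X @ b),
                            np.zeros(X.shape[1]), method="lm",
                            xtol=1e-14, ftol=1e-14)
        rel = np.abs(m.beta_hat.to_numpy() - nls.x) / np.maximum(np.abs(nls.x), 1e-8)
        assert rel.max() < 1e-4

    def test_days_scale_predictions_strictly_positive(self, glmm20, registry20):
        pred = predict_los(glmm20, registry20, mode="FE", scale="days")
        assert (pred.values > 0).all()

    def test_converged_with_positive_variances(self, glmm20):
        assert glmm20.converged
        assert glmm20.tau2_hat > 0 and glmm20.sigma2_hat > 0
        assert glmm20.n_iter <= 2000


class TestPredictLos:
    def test_lmm_re_additivity(self, lmm20, registry20):
        fe = predict_los(lmm20, registry20, mode="FE")
        re = predict_los(lmm20, registry20, mode="RE")
        offsets = registry20.patients.loc[fe.values.index, "icu_id"].map(
            lmm20.re.set_index("icu_id")["re"])
        assert np.allclose(re.values, fe.values + offsets, atol=1e-12)

    def test_fe_equals_re_when_intercepts_zero(self, small_spec):
        reg = generate_registry(simple_sim_config(3, 80, tau2=0.0, seed=7))
        m = fit_glmm_log_gaussian(reg, small_spec, fix_tau2_zero=True)
        fe = predict_los(m, reg, mode="FE", scale="days")
        re = predict_los(m, reg, mode="RE", scale="days")
        assert np.allclose(fe.values, re.values)

    def test_unseen_site_in_re_mode_is_named(self, lmm20, registry20):
        extra = registry20.patients.head(3).copy()
        extra["icu_id"] = 999
        reg = type(registry20)(
            patients=pd.concat([registry20.patients, extra], ignore_index=True),
            sites=pd.concat([registry20.sites, pd.DataFrame(
                {"icu_id": [999], "hosp_class": ["MET"], "annual_volume": [3]})],
                ignore_index=True))
        with pytest.raises(KeyError, match="999"):
            predict_los(lmm20, reg, mode="RE")

    def test_lmm_days_scale_refused(self, lmm20, registry20):
        with pytest.raises(ValueError, match="log scale"):
            predict_los(lmm20, registry20, mode="FE", scale="days")


class TestRSquared:
    def test_perfect_and_anticorrelated(self):
        x = np.array([1.0, 2, 3, 4])
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(x, -x) == pytest.approx(1.0)  # documented quirk

    def test_hand_oracle(self):
        # cov = 11, var_o = 14, var_p = 10 => r^2 = 121/140
        assert r_squared([1, 2, 3, 6], [1, 2, 4, 5]) == pytest.approx(121 / 140)

    def test_icu_level_averages_first(self):
        obs = [1, 3, 10, 20]
        pred = [2, 2, 16, 14]
        # icu means: (2, 15) vs (2, 15) => perfect at ICU level
        assert r_squared(obs, pred, level="icu",
                         icu_ids=[1, 1, 2, 2]) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        assert math.isnan(r_squared([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            r_squared([1, 2], [1, 2, 3])


class TestSplitSampleValidation:
    def test_seeded_split_reproducible(self, registry20, small_spec):
        a = split_sample_validation(registry20, small_spec, "lmm", seed=3)
        b = split_sample_validation(registry20, small_spec, "lmm", seed=3)
        assert a.development_sites == b.development_sites
        assert a.r2_development == b.r2_development

    def test_sites_disjoint_and_exhaustive(self, registry20, small_spec):
        rep = split_sample_validation(registry20, small_spec, "lmm", seed=3)
        dev, val = set(rep.development_sites), set(rep.validation_sites)
        assert dev.isdisjoint(val)
        assert dev | val == set(registry20.sites["icu_id"])
        assert len(dev) == round(0.6 * registry20.n_sites)

    def test_homogeneous_generator_gives_similar_r2(self, default_registry,
                                                    small_spec):
        # development uses in-sample RE predictions, validation out-of-sample
        # FE ones, so the structural gap is about the site-variance share of
        # total log-LOS variance (tau2/Var ~ 0.045 here) plus sampling noise
        rep = split_sample_validation(default_registry, small_spec, "lmm",
                                      seed=3)
        assert 0 <= rep.r2_validation <= 1
        assert rep.r2_development > rep.r2_validation - 0.02
        assert abs(rep.r2_development - rep.r2_validation) < 0.08

    def test_degenerate_fractions_rejected(self, registry20, small_spec):
        with pytest.raises(ValueError):
            split_sample_validation(registry20, small_spec, fraction=1.0)
        with pytest.raises(ValueError):
            split_sample_validation(registry20, small_spec, fraction=0.01)


class TestResidualDiagnostics:
    def test_perfect_fit_residuals_zero(self, small_spec):
        cfg = simple_sim_config(5, 100, beta=SMALL_BETA, gen_terms=SMALL_TERMS,
                                tau2=0.0, sigma2=1.0, seed=2)
        reg = generate_registry(cfg)
        eta = linear_predictor(reg.patients, small_spec, SMALL_BETA)
        reg.patients["los_days"] = np.exp(eta)
        m = fit_lmm(reg, small_spec)
        table, summary = residual_diagnostics(m, reg)
        assert np.abs(table["residual"]).max() < 1e-6

    def test_lmm_standardized_mean_near_zero(self, lmm20, registry20):
        _, summary = residual_diagnostics(lmm20, registry20)
        assert abs(summary["mean"]) < 0.02

    def test_glmm_gaussian_deviance_centered(self):
        reg = single_site_registry(seed=2)
        m = fit_glmm_log_gaussian(reg, ModelSpec(fixed_terms=[], interactions=[]))
        table, _ = residual_diagnostics(m, reg)
        assert table["deviance"].sum() == pytest.approx(0.0, abs=1e-6)
        # gaussian family: Anscombe residual reduces to y - mu
        assert (table["deviance"] == table["anscombe"]).all()


class TestNormalityCheck:
    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            normality_check(rng.standard_normal(5000)).rejected
            for _ in range(100))
        assert rejections <= 10  # "not rejected" in >= 90% of replicates

    def test_gross_non_normality_rejected(self):
        x = np.random.default_rng(1).exponential(1.0, 5000)
        assert normality_check(x).rejected

    def test_log_los_gamma_noise_rejected(self):
        # with gamma LOS noise, log-LOS is not normal and the omnibus test
        # should say so
        cfg = simple_sim_config(10, 500, noise_family="gamma", seed=3)
        los = generate_registry(cfg).patients["los_days"]
        assert normality_check(np.log(los), seed=0).rejected

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            normality_check(np.ones(100))
        with pytest.raises(ValueError):
            normality_check(np.arange(5))
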