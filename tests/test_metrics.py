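"""BCa bootstrap and per-ICU quality-metric tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from iculos import (bca_interval, omelos_table, ralosr_arith_table,
                    ralosr_geo_table, site_re_table, point_ranks)
from iculos.metrics import _bca_core
from conftest import registry_from_los


def mean_stat(s):
    return float(np.mean(s))


class TestBcaInterval:
    def test_constant_sample_zero_width(self):
        assert bca_interval(np.array([2.0, 2, 2, 2]), mean_stat) == (2.0, 2.0, 2.0)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(0).exponential(1, 40)
        assert bca_interval(x, mean_stat, seed=7) == bca_interval(x, mean_stat, seed=7)
        assert bca_interval(x, mean_stat, seed=7) != bca_interval(x, mean_stat, seed=8)

    def test_symmetric_sample_bias_term_small(self):
        # for a symmetric statistic the bootstrap is median-unbiased => z0 ~ 0
        x = np.random.default_rng(3).standard_normal(200)
        out = _bca_core(x, mean_stat, B=2000, alpha=0.05,
                        rng=np.random.default_rng(1))
        z0 = stats.norm.ppf(np.mean(out["theta_star"] < out["point"]))
        assert abs(z0) < 0.1

    def test_matches_scipy_bca_cross_check(self):
        # independent oracle: scipy's own BCa implementation on the same data
        x = np.random.default_rng(5).exponential(1, 60)
        _, lo, hi = bca_interval(x, mean_stat, B=4000, seed=2)
        ref = stats.bootstrap((x,), np.mean, n_resamples=4000, method="BCa",
                              random_state=np.random.default_rng(3))
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.05)

    def test_infinite_bias_falls_back_to_percentile(self):
        # statistic = sample min: no resample can fall below the estimate
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = _bca_core(x, lambda s: float(np.min(s)), B=200, alpha=0.05,
                        rng=np.random.default_rng(0))
        assert out["method"] == "percentile"

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bca_interval(np.array([1.0]), mean_stat)


class TestMetricTables:
    def test_omelos_hand_example(self):
        reg = registry_from_los({1: [2.0, 4.0]})
        pred = pd.Series([1.0, 3.0], index=reg.patients.index)
        t = omelos_table(reg, pred, B=200).table
        assert t.loc[0, "point"] == pytest.approx(1.0)

    def test_ralosr_hand_examples(self):
        reg = registry_from_los({1: [2.0, 4.0]})
        pred = pd.Series([1.0, 3.0], index=reg.patients.index)
        t = ralosr_arith_table(reg, pred, B=200).table
        assert t.loc[0, "point"] == pytest.approx(1.5)
        # geometric: obs {1,4} (GM 2) vs predicted log {0,0} (GM 1)
        reg2 = registry_from_los({1: [1.0, 4.0]})
        pl = pd.Series([0.0, 0.0], index=reg2.patients.index)
        g = ralosr_geo_table(reg2, pl, B=200).table
        assert g.loc[0, "point"] == pytest.approx(2.0)

    def test_perfect_predictions_are_null(self):
        reg = registry_from_los({1: [2.0, 5.0, 3.0], 2: [1.0, 6.0]})
        pred = reg.patients["los_days"].astype(float)
        om = omelos_table(reg, pred, B=200).table
        ra = ralosr_arith_table(reg, pred, B=200).table
        assert np.allclose(om["point"], 0) and np.allclose(om["ci_low"], 0) \
            and np.allclose(om["ci_high"], 0)
        assert np.allclose(ra["point"], 1.0)
        gl = ralosr_geo_table(reg, np.log(pred), B=200).table
        assert np.allclose(gl["point"], 1.0)

    def test_identity_coupling(self, registry20, fe_days20):
        # omelos = 0 <=> ralosr_arith = 1 on the same predictions
        om = omelos_table(registry20, fe_days20, B=50, seed=1).table
        ra = ralosr_arith_table(registry20, fe_days20, B=50, seed=1).table
        assert np.allclose(np.sign(om["point"]), np.sign(ra["point"] - 1.0))

    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(min_value=0.05, max_value=20.0,
                       allow_nan=False, allow_infinity=False))
    def test_scale_equivariance(self, c):
        # scaling all observed and predicted LOS by c scales omelos by c and
        # leaves both RALOSR variants unchanged
        obs = np.array([2.0, 5.0, 3.0, 8.0])
        pred = np.array([3.0, 4.0, 2.0, 6.0])
        om = np.mean(obs) - np.mean(pred)
        ra = np.mean(obs) / np.mean(pred)
        geo = np.exp(np.mean(np.log(obs)) - np.mean(np.log(pred)))
        assert np.mean(c * obs) - np.mean(c * pred) == pytest.approx(c * om)
        assert np.mean(c * obs) / np.mean(c * pred) == pytest.approx(ra)
        assert np.exp(np.mean(np.log(c * obs)) - np.mean(np.log(c * pred))) \
            == pytest.approx(geo)

    def test_geo_vs_arith_can_invert_rankings(self):
        # a skewed ICU ranks high on the arithmetic ratio but neutral on the
        # geometric one: the two RALOSR variants are not rank-monotone
        reg = registry_from_los({1: [1.0, 100.0], 2: [5.0, 5.0], 3: [20.0, 20.0]})
        pred_days = pd.Series(10.0, index=reg.patients.index)
        pred_log = pd.Series(np.log(10.0), index=reg.patients.index)
        ra = ralosr_arith_table(reg, pred_days, B=100).table
        rg = ralosr_geo_table(reg, pred_log, B=100).table
        ranks_a = point_ranks(ra["point"].to_numpy())
        ranks_g = point_ranks(rg["point"].to_numpy())
        assert not np.array_equal(ranks_a, ranks_g)
        # ICU 1 vs ICU 3 swap order between the variants
        assert (ra["point"][0] > ra["point"][2]) and (rg["point"][0] < rg["point"][2])

    def test_single_patient_wald_fallback(self):
        reg = registry_from_los({1: [2.0], 2: [3.0, 5.0]})
        t = omelos_table(reg, pd.Series([1.0, 2.0, 4.0],
                                        index=reg.patients.index), B=100).table
        assert t.set_index("icu_id").loc[1, "ci_method"] == "wald"
        assert t.set_index("icu_id").loc[2, "ci_method"] == "bca"

    def test_table_shape_contract(self, registry20, fe_days20):
        mt = omelos_table(registry20, fe_days20, B=50, seed=0)
        t = mt.table
        assert len(t) == registry20.n_sites
        assert (t["metric_kind"] == "omelos").all()
        assert ((t["ci_low"] <= t["point"]) & (t["point"] <= t["ci_high"])).all()


class TestSiteReTable:
    def test_wald_interval_hand_example(self, glmm20):
        mt = site_re_table(glmm20)
        row = mt.table.iloc[0]
        z = stats.norm.ppf(0.975)
        assert row["ci_low"] == pytest.approx(row["point"] - z * glmm20.re["se"][0])
        # hand check: re 0.5, se 0.1 -> [0.304, 0.696]
        assert 0.5 - z * 0.1 == pytest.approx(0.304, abs=1e-3)
        assert 0.5 + z * 0.1 == pytest.approx(0.696, abs=1e-3)

    def test_zero_se_zero_width(self, glmm20):
        m = type(glmm20)(**{**glmm20.__dict__,
                            "re": pd.DataFrame({"icu_id": [1], "re": [0.0],
                                                "se": [0.0], "n": [10]})})
        t = site_re_table(m).table
        assert (t["ci_low"] == 0).all() and (t["ci_high"] == 0).all()

    def test_blups_center_near_zero(self, glmm20, lmm20):
        for m in (glmm20, lmm20):
            assert abs(site_re_table(m).table["point"].mean()) < 0.05

    def test_missing_se_rejected(self, glmm20):
        m = type(glmm20)(**{**glmm20.__dict__,
                            "re": pd.DataFrame({"icu_id": [1], "re": [0.1],
                                                "se": [np.nan], "n": [10]})})
        with pytest.raises(ValueError):
            site_re_table(m)
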