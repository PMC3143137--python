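import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from pathmeta.meta import (
    EffectRecord,
    bonferroni_threshold,
    correlation_se,
    forest_table,
    pearson_correlation,
    pool_hazard_ratios,
    pool_random_effects,
)
from pathmeta.survival import HREffect


def corr_effect(estimate, se, study="s", n=None):
    return EffectRecord(study=study, kind="correlation", estimate=estimate, se=se, n=n)


def dl_oracle(theta, se):
    """Step-by-step DerSimonian-Laird computation, independent of the package."""
    theta, se = np.asarray(theta, float), np.asarray(se, float)
    w = [1.0 / s**2 for s in se]
    fixed = sum(wi * ti for wi, ti in zip(w, theta)) / sum(w)
    q = sum(wi * (ti - fixed) ** 2 for wi, ti in zip(w, theta))
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(theta) - 1)) / c)
    wr = [1.0 / (s**2 + tau2) for s in se]
    pooled = sum(wi * ti for wi, ti in zip(wr, theta)) / sum(wr)
    return pooled, q, tau2


class TestCorrelationSe:
    def test_closed_form_values(self):
        assert correlation_se(0.0, 101) == pytest.approx(0.1, abs=1e-15)
        # (1 - 0.65^2)/sqrt(19) = 0.5775/sqrt(19)
        assert correlation_se(0.65, 20) == pytest.approx(0.5775 / math.sqrt(19), rel=1e-12)

    def test_vanishes_toward_perfect_correlation(self):
        assert correlation_se(0.9999, 10) < 1e-3

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            correlation_se(1.0, 10)
        with pytest.raises(ValueError):
            correlation_se(0.5, 1)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        assert pearson_correlation(x, x).estimate == pytest.approx(1.0)
        assert pearson_correlation(x, -x).estimate == pytest.approx(-1.0)

    def test_matches_sum_of_products_oracle(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        n = len(x)
        num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
        den = math.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * math.sqrt(
            n * np.sum(y * y) - np.sum(y) ** 2
        )
        rec = pearson_correlation(x, y)
        assert rec.estimate == pytest.approx(num / den, abs=1e-12)
        assert rec.se == pytest.approx(correlation_se(rec.estimate, n))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPoolRandomEffects:
    def test_two_study_hand_oracle(self):
        effects = [corr_effect(0.0, 0.1), corr_effect(0.9, 0.1)]
        # w = 100 each; fixed = 0.45; Q = 100*0.45^2*2 = 40.5; C = 100
        # tau2 = 39.5/100; pooled = mean by symmetry of equal SEs
        res = pool_random_effects(effects)
        pooled, q, tau2 = dl_oracle([0.0, 0.9], [0.1, 0.1])
        assert res.pooled == pytest.approx(pooled, abs=1e-10)
        assert res.q == pytest.approx(q, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)

    def test_matches_statsmodels_dl(self, rng):
        theta = rng.uniform(-0.5, 0.5, 7)
        se = rng.uniform(0.05, 0.3, 7)
        effects = [corr_effect(t, s) for t, s in zip(theta, se)]
        res = pool_random_effects(effects)
        sm = combine_effects(theta, se**2, method_re="dl")
        assert res.pooled == pytest.approx(sm.mean_effect_re, abs=1e-10)
        assert res.tau2 == pytest.approx(sm.tau2, abs=1e-10)
        sm_weights = sm.summary_frame().loc[[str(i) for i in range(7)], "w_re"] \
            if "0" in sm.summary_frame().index else sm.summary_frame()["w_re"][:7]
        np.testing.assert_allclose(res.weights, np.asarray(sm_weights, float), atol=1e-10)

    def test_identical_effects_have_no_heterogeneity(self):
        res = pool_random_effects([corr_effect(0.4, 0.1) for _ in range(3)])
        assert res.pooled == pytest.approx(0.4)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0

    def test_single_effect_passthrough(self):
        res = pool_random_effects([corr_effect(0.3, 0.15)])
        assert (res.pooled, res.tau2, res.df) == (0.3, 0.0, 0)
        assert res.ci95 == pytest.approx((0.3 - 1.96 * 0.15, 0.3 + 1.96 * 0.15))

    def test_zero_effects_rejected(self):
        with pytest.raises(ValueError, match="no effects"):
            pool_random_effects([])

    def test_equal_se_homogeneous_estimates_pool_to_mean(self):
        ests = [0.50, 0.52, 0.51]
        res = pool_random_effects([corr_effect(e, 0.3) for e in ests])
        assert res.tau2 == 0.0  # Q below df, truncated
        assert res.pooled == pytest.approx(np.mean(ests), abs=1e-12)
        np.testing.assert_allclose(res.weights, 1 / 3, atol=1e-12)

    @given(
        data=st.lists(
            st.tuples(st.floats(-0.9, 0.9), st.floats(0.02, 0.5)), min_size=2, max_size=8
        )
    )
    def test_convexity_and_tau2_truncation(self, data):
        effects = [corr_effect(t, s) for t, s in data]
        res = pool_random_effects(effects)
        ests = [t for t, _ in data]
        assert min(ests) - 1e-12 <= res.pooled <= max(ests) + 1e-12
        assert res.tau2 >= 0.0
        if res.q <= res.df:
            assert res.tau2 == 0.0
        assert np.sum(res.weights) == pytest.approx(1.0)

    def test_fisher_and_raw_agree_for_small_effects(self, rng):
        rhos = rng.uniform(-0.3, 0.3, 6)
        ns = rng.integers(50, 300, 6)
        effects = [
            corr_effect(r, correlation_se(r, int(n)), n=int(n))
            for r, n in zip(rhos, ns)
        ]
        raw = pool_random_effects(effects, scale="raw_rho").pooled_natural
        fz = pool_random_effects(effects, scale="fisher_z").pooled_natural
        assert abs(raw - fz) < 0.02

    def test_mixed_kinds_rejected(self):
        effects = [
            corr_effect(0.3, 0.1),
            EffectRecord(study="x", kind="log_hr", estimate=0.1, se=0.1),
        ]
        with pytest.raises(ValueError, match="mixed"):
            pool_random_effects(effects)


class TestPoolHazardRatios:
    @staticmethod
    def hr_effect(hr, se, study=""):
        log_hr = math.log(hr)
        return HREffect(
            log_hr=log_hr,
            se=se,
            hr=hr,
            ci95=(math.exp(log_hr - 1.96 * se), math.exp(log_hr + 1.96 * se)),
            p_value=0.5,
            n=50,
            events=30,
            study=study,
        )

    def test_single_study_keeps_hr_and_ci(self):
        se = math.log(1.0 / 0.8) / 1.96  # chosen so the CI is (0.64, 1.0)
        eff = self.hr_effect(0.8, se)
        res = pool_hazard_ratios([eff])
        assert res.pooled_natural == pytest.approx(0.8)
        assert res.ci95_natural[1] == pytest.approx(1.0)
        assert res.ci95_natural[0] == pytest.approx(0.8 * 0.8)

    def test_symmetric_pair_pools_to_null(self):
        res = pool_hazard_ratios(
            [self.hr_effect(math.exp(0.4), 0.2), self.hr_effect(math.exp(-0.4), 0.2)]
        )
        assert res.pooled == pytest.approx(0.0, abs=1e-12)
        assert res.pooled_natural == pytest.approx(1.0)

    def test_recovers_common_hazard_ratio(self):
        # 6 studies around a true HR of 0.75; pooled estimate lands nearby
        true_log = math.log(0.75)
        pooled_logs = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            effs = [
                self.hr_effect(math.exp(rng.normal(true_log, 0.15)), 0.15, study=f"s{i}")
                for i in range(6)
            ]
            pooled_logs.append(pool_hazard_ratios(effs).pooled)
        mean_pooled = np.mean(pooled_logs)
        mc_se = np.std(pooled_logs) / math.sqrt(len(pooled_logs))
        assert abs(mean_pooled - true_log) < 3 * mc_se + 0.01


class TestForestTable:
    def test_study_rows_plus_pooled_row(self):
        effects = [corr_effect(0.2, 0.1, study="a"), corr_effect(0.6, 0.2, study="b")]
        res = pool_random_effects(effects)
        table = forest_table(res, effects)
        assert list(table["study"]) == ["a", "b", "pooled"]
        assert table["weight_pct"].iloc[:2].sum() == pytest.approx(100.0)
        assert table["tau2"].iloc[-1] == pytest.approx(res.tau2)


def test_bonferroni_threshold_for_twenty_pathways():
    assert bonferroni_threshold(20) == pytest.approx(0.0025)
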