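"""Decision-tree statistics: summary t, Mann-Whitney, Yates chi-square,
ANOVA + Dunnett."""

import numpy as np
import pytest
import scipy.stats

import lungspan as ls
from lungspan.groupstats import (ContingencyTable2x2, SummaryStats,
                                 dunnett_max_t_null)


class TestCheckAssumptions:
    def test_normal_samples_routed_to_t(self):
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rep = ls.check_assumptions(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
            ok += rep.recommendation in ("t-test", "welch-t")
        # Shapiro at alpha 0.05 per sample: expected pass rate 0.95^2
        assert ok >= 85

    def test_exponential_samples_routed_to_mann_whitney(self):
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rep = ls.check_assumptions(rng.exponential(1, 50),
                                       rng.exponential(1, 50))
            ok += rep.recommendation == "mann-whitney"
        assert ok >= 90

    def test_equal_variances_f_boundary(self):
        x = np.array([1.0, 2, 3, 4, 5])
        rep = ls.check_assumptions(x, x + 10)
        assert rep.variance_ratio.statistic == pytest.approx(1.0)
        assert rep.variance_ratio.p == pytest.approx(1.0)

    def test_constant_sample_falls_back_to_mann_whitney(self):
        rep = ls.check_assumptions([1.0, 1, 1, 1], [1.0, 2, 3, 4])
        assert rep.recommendation == "mann-whitney"


class TestSummaryT:
    def test_equal_means_t_zero_p_one(self):
        res = ls.two_sample_t_from_summary(SummaryStats(5, 1, 10),
                                           SummaryStats(5, 2, 12))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_pooled_matches_raw_data_t_exactly(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 18), rng.normal(0.5, 1.2, 16)
        res = ls.two_sample_t_from_summary(
            SummaryStats(x.mean(), x.std(ddof=1), x.size),
            SummaryStats(y.mean(), y.std(ddof=1), y.size), pooled=True)
        ref = scipy.stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_welch_satterthwaite_df(self):
        a, b = SummaryStats(1.0, 1.0, 10), SummaryStats(2.0, 3.0, 20)
        res = ls.two_sample_t_from_summary(a, b, pooled=False)
        ref = scipy.stats.ttest_ind_from_stats(1, 1, 10, 2, 3, 20,
                                               equal_var=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)
        assert 9 < res.df < 28 and res.df != 28

    @pytest.mark.parametrize("a,b,expected_p", [
        # cohort lung-function rows: mean, SD, n per group -> printed p
        ((3.17, 0.58, 18), (2.50, 0.64, 16), 0.003),   # FVC (L)
        ((3.07, 0.56, 18), (2.47, 0.64, 16), 0.007),   # VC (L)
        ((81.72, 5.43, 18), (77.50, 6.37, 16), 0.045),  # FEV1/FVC (%)
        ((5.99, 1.57, 18), (4.69, 1.51, 16), 0.020),   # PEF (L/s)
        ((0.87, 0.31, 18), (0.63, 0.38, 16), 0.051),   # ERV (L)
    ])
    def test_cohort_summary_rows(self, a, b, expected_p):
        res = ls.two_sample_t_from_summary(SummaryStats(*a), SummaryStats(*b))
        assert res.p == pytest.approx(expected_p, abs=0.002)

    def test_cohort_mvv_below_1e4(self):
        res = ls.two_sample_t_from_summary(
            SummaryStats(108.30, 22.58, 18), SummaryStats(68.57, 20.64, 16))
        assert res.p < 0.0001


class TestMannWhitney:
    def test_exact_enumeration_small_samples(self):
        res = ls.mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p == pytest.approx(0.1)  # 2/C(6,3)
        assert "exact" in res.method

    def test_identical_samples_p_one(self):
        res = ls.mann_whitney_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.p == pytest.approx(1.0)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float)
        res = ls.mann_whitney_test(x, y)
        assert "asymptotic" in res.method
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue)

    def test_power_at_one_sd_shift(self):
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 50)
            y = rng.normal(1, 1, 50)
            hits += ls.mann_whitney_test(x, y).p < 0.05
        assert hits / n_sims >= 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ls.mann_whitney_test([], [1.0])


def yates_cellwise(a, b, c, d):
    """Independent oracle: sum over cells of (max(|O-E|-0.5, 0))^2 / E."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    return (adj ** 2 / exp).sum()


class TestYatesChiSquare:
    def test_cohort_sex_table(self):
        res = ls.yates_chi_square(ContingencyTable2x2(3, 15, 8, 8))
        assert res.p == pytest.approx(0.088, abs=0.001)

    def test_balanced_table_zero_statistic(self):
        res = ls.yates_chi_square(ContingencyTable2x2(5, 5, 5, 5))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_zero_marginal_p_one_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="lungspan"):
            res = ls.yates_chi_square(ContingencyTable2x2(0, 0, 3, 4))
        assert res.p == 1.0
        assert "marginal" in caplog.text

    def test_matches_cellwise_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 40, size=4)
            got = ls.yates_chi_square(ContingencyTable2x2(a, b, c, d))
            assert got.statistic == pytest.approx(yates_cellwise(a, b, c, d),
                                                  rel=1e-10, abs=1e-12)

    def test_matches_scipy_contingency_correction(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 30, size=4)
            got = ls.yates_chi_square(ContingencyTable2x2(a, b, c, d))
            chi2, p, _, _ = scipy.stats.chi2_contingency(
                [[a, b], [c, d]], correction=True)
            assert got.statistic == pytest.approx(chi2, rel=1e-10, abs=1e-12)
            assert got.p == pytest.approx(p, rel=1e-10, abs=1e-12)


class TestAnovaDunnett:
    def test_identical_groups_f_zero_p_one(self):
        g = np.array([1.0, 2, 3, 4, 5])
        anova, comps = ls.anova_dunnett([g, g.copy(), g.copy()], 0, seed=0)
        assert anova.statistic == pytest.approx(0.0)
        assert all(c.p == pytest.approx(1.0, abs=1e-6) for c in comps)

    def test_two_groups_reduce_to_two_sample_t(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 15), rng.normal(0.8, 1, 15)
        _, comps = ls.anova_dunnett([x, y], 0, n_draws=200_000, seed=2)
        ref = scipy.stats.ttest_ind(y, x, equal_var=True)
        assert comps[0].p == pytest.approx(ref.pvalue, abs=0.01)

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 12) for m in (0, 0.3, 0.9, 1.5)]
        _, comps = ls.anova_dunnett(groups, 0, seed=3)
        for c in comps:
            assert c.p >= c.extra["p_unadjusted"] - 1e-12
            assert c.extra["mc_se"] < 0.005

    def test_matches_scipy_dunnett(self):
        """Monte-Carlo adjusted p agrees with scipy's Dunnett
        implementation (independent multivariate-t route)."""
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 20) for m in (0, 0.5, 0.8, 0.2)]
        _, comps = ls.anova_dunnett(groups, 0, n_draws=400_000, seed=5)
        ref = scipy.stats.dunnett(*groups[1:], control=groups[0],
                                  alternative="two-sided")
        for c, p_ref in zip(comps, ref.pvalue):
            assert c.p == pytest.approx(p_ref, abs=0.01)

    def test_control_index_validated(self):
        with pytest.raises(ValueError, match="control index"):
            ls.anova_dunnett([np.ones(3), np.ones(3)], 5)

    def test_fwer_near_nominal_on_null(self):
        """FWER at alpha 0.05 for 4 balanced null groups (400 sims here;
        the 2000-sim version lives in the acceptance suite)."""
        null = dunnett_max_t_null([10] * 4, 0, n_draws=200_000,
                                  rng=np.random.default_rng(9))
        crit = np.quantile(null, 0.95)
        rng = np.random.default_rng(10)
        hits = 0
        n_sims = 400
        for _ in range(n_sims):
            g = rng.standard_normal((4, 10))
            means = g.mean(axis=1)
            s2 = ((g - means[:, None]) ** 2).sum() / (40 - 4)
            t = (means[1:] - means[0]) / np.sqrt(s2 * (2 / 10))
            hits += np.abs(t).max() > crit
        assert abs(hits / n_sims - 0.05) < 0.03
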