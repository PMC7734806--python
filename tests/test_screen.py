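import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metscreen.screen import (
    ScreenError,
    adaptive_p,
    anderson_darling_a2,
    anderson_darling_critical,
    chi_square_independence,
    count_leave_k_out,
    f_test_p,
    ks_same_shape_p,
    leave_k_out_fdr,
    pooled_t_from_stats,
    roc_auc,
    run_screen,
    select_test,
    two_sample_p,
)


# -- primitives vs scipy (dual-route checks) ----------------------------------


class TestPrimitivesAgainstScipy:
    def test_anderson_darling_matches_scipy(self, rng):
        for n in (10, 30, 57):
            x = rng.normal(2.0, 3.0, n)
            ref = stats.anderson(x, dist="norm", method="interpolate")
            assert anderson_darling_a2(x) == pytest.approx(ref.statistic, rel=1e-10)

    def test_anderson_critical_matches_scipy(self):
        import warnings

        x = np.random.default_rng(0).normal(size=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = stats.anderson(x, dist="norm")
        idx = list(ref.significance_level).index(5.0)
        assert anderson_darling_critical(25, 0.05) == pytest.approx(
            ref.critical_values[idx], abs=5e-4
        )

    def test_t_tests_match_scipy(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 2, 29)
        t, p = two_sample_p(x, y, "t_eq")
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue), rel=1e-12)
        t, p = two_sample_p(x, y, "t_neq")
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue), rel=1e-12)

    def test_mann_whitney_matches_scipy(self, rng):
        x = rng.integers(0, 8, 30).astype(float)  # heavy ties
        y = rng.integers(0, 8, 29).astype(float)
        u, p = two_sample_p(x, y, "mw")
        ref = stats.mannwhitneyu(x, y, method="asymptotic")
        assert (u, p) == pytest.approx((ref.statistic, ref.pvalue), rel=1e-12)

    def test_f_test_matches_scipy_distribution(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0, 3, 25)
        f = np.var(x, ddof=1) / np.var(y, ddof=1)
        ref = 2 * min(stats.f.cdf(f, 19, 24), stats.f.sf(f, 19, 24))
        assert f_test_p(x, y) == pytest.approx(ref, rel=1e-12)

    def test_ks_close_to_scipy_asymptotic(self, rng):
        x, y = rng.exponential(1, 40), rng.normal(0, 1, 45)
        ref = stats.ks_2samp(x - np.median(x), y - np.median(y), method="asymp")
        assert ks_same_shape_p(x, y) == pytest.approx(ref.pvalue, abs=0.02)

    def test_chi2_matches_scipy(self):
        table = [[10, 20, 5], [8, 12, 14]]
        stat, p = chi_square_independence(table)
        ref = stats.chi2_contingency(np.asarray(table), correction=False)
        assert (stat, p) == pytest.approx((ref.statistic, ref.pvalue), rel=1e-12)


# -- select_test decision tree -------------------------------------------------


class TestSelectTest:
    def scenario_rate(self, sampler_x, sampler_y, n_rep=40):
        counts = {}
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            s = select_test(sampler_x(r), sampler_y(r))
            counts[s] = counts.get(s, 0) + 1
        return {k: v / n_rep for k, v in counts.items()}

    def test_null_gaussian_prefers_pooled_t(self):
        # joint non-rejection of two AD tests and one F test at alpha=0.05
        # has probability ~0.95^3 ~ 0.86, so t_eq dominates but cannot hit 0.9
        rates = self.scenario_rate(
            lambda r: r.normal(0, 1, 200), lambda r: r.normal(0, 1, 200)
        )
        assert rates.get("t_eq", 0) >= 0.8
        assert max(rates, key=rates.get) == "t_eq"

    def test_variance_ratio_nine_prefers_welch(self):
        rates = self.scenario_rate(
            lambda r: r.normal(0, 1, 200), lambda r: r.normal(0, 3, 200)
        )
        assert max(rates, key=rates.get) == "t_neq"

    def test_shifted_exponential_prefers_mann_whitney(self):
        rates = self.scenario_rate(
            lambda r: r.exponential(1, 200), lambda r: r.exponential(1, 200) + 0.5
        )
        assert max(rates, key=rates.get) == "mw"

    def test_different_shapes_prefer_welch_dagger(self):
        rates = self.scenario_rate(
            lambda r: r.exponential(1, 200), lambda r: r.uniform(0, 2, 200)
        )
        assert max(rates, key=rates.get) == "t_neq_dagger"

    def test_small_sample_errors(self):
        with pytest.raises(ScreenError, match="too small"):
            select_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])

    def test_constant_sample_falls_back_to_mw(self):
        with pytest.warns(UserWarning, match="constant"):
            assert select_test([2.0] * 10, [1.0, 2.0, 3.0, 4.0, 5.0]) == "mw"


# -- two_sample_p --------------------------------------------------------------


class TestTwoSampleP:
    def test_printed_summary_stats_round_to_table_value(self):
        # summary statistics taken from a published two-group comparison
        t, p = pooled_t_from_stats(1.89, 0.22, 30, 1.72, 0.24, 29)
        assert p == pytest.approx(0.0064, abs=5e-4)
        assert round(p, 2) == 0.01

    def test_identical_samples_give_p_one(self, rng):
        x = rng.normal(size=20)
        for scenario in ("t_eq", "t_neq", "t_neq_dagger"):
            _, p = two_sample_p(x, x.copy(), scenario)
            assert p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        _, p = two_sample_p([2.0] * 10, [2.0] * 12, "t_eq")
        assert p == 1.0

    def test_mw_close_to_exact_permutation_4v4(self, rng):
        # oracle: exhaustive two-sided permutation p over all C(8,4)=70 splits
        x = np.array([0.1, 0.9, 1.7, 2.5])
        y = np.array([1.1, 1.9, 3.0, 3.4])
        u_obs, p_asym = two_sample_p(x, y, "mw")
        pooled = np.concatenate([x, y])

        def u_of(idx):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(8) if i not in idx]]
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

        us = [u_of(c) for c in combinations(range(8), 4)]
        mid = len(x) * len(y) / 2
        p_exact = np.mean([abs(u - mid) >= abs(u_obs - mid) - 1e-12 for u in us])
        assert p_asym == pytest.approx(p_exact, abs=0.02)


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_printed_2x2_counts_significant(self):
        # 10/30 vs 3/29 "uses / does not use" contingency
        stat, p = chi_square_independence([[10, 20], [3, 26]])
        assert p <= 0.05
        assert round(p, 2) == 0.03

    def test_matches_squared_two_proportion_z(self):
        a, b, c, d = 12, 18, 5, 25
        stat, _ = chi_square_independence([[a, b], [c, d]])
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        pp = (a + c) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z**2, rel=1e-12)

    def test_zero_margin_errors(self):
        with pytest.raises(ScreenError, match="degenerate"):
            chi_square_independence([[0, 0], [5, 5]])


# -- leave-k-out FDR -----------------------------------------------------------


def oracle_fdr(x, y, alpha=0.05, depths=(1, 2)):
    """Brute-force re-implementation on scipy.stats primitives."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ps = []
    for d in depths:
        for removed in combinations(range(len(pooled)), d):
            keep = [i for i in range(len(pooled)) if i not in removed]
            xs = pooled[[i for i in keep if i < n1]]
            ys = pooled[[i for i in keep if i >= n1]]
            if len(xs) < 4 or len(ys) < 4:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a5x = stats.anderson(xs)
                a5y = stats.anderson(ys)
            crit = lambda r: r.critical_values[list(r.significance_level).index(5.0)]
            if a5x.statistic <= crit(a5x) and a5y.statistic <= crit(a5y):
                f = np.var(xs, ddof=1) / np.var(ys, ddof=1)
                pf = 2 * min(
                    stats.f.cdf(f, len(xs) - 1, len(ys) - 1),
                    stats.f.sf(f, len(xs) - 1, len(ys) - 1),
                )
                equal_var = pf >= 0.05
                ps.append(stats.ttest_ind(xs, ys, equal_var=equal_var).pvalue)
            else:
                pks = ks_same_shape_p(xs, ys)
                if pks < 0.05:
                    ps.append(stats.ttest_ind(xs, ys, equal_var=False).pvalue)
                else:
                    ps.append(stats.mannwhitneyu(xs, ys, method="asymptotic").pvalue)
    return float(np.mean([p > alpha for p in ps]))


class TestLeaveKOut:
    def test_enumeration_count_59_is_1770(self):
        assert count_leave_k_out(59, (1, 2)) == 1770

    def test_pvalue_count_matches_enumeration(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 29)
        _, ps = leave_k_out_fdr(x, y, depths=(1, 2), return_pvalues=True)
        assert len(ps) == 1770

    def test_strong_separation_gives_zero(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(20, 1, 15)
        assert leave_k_out_fdr(x, y, depths=(1, 2)) == 0.0

    def test_matches_bruteforce_oracle_n20(self, rng):
        # a marginal effect so deletions flip significance both ways
        x = rng.normal(0.0, 1.0, 10)
        y = rng.normal(1.0, 1.0, 10)
        ours = leave_k_out_fdr(x, y, depths=(1, 2))
        ref = oracle_fdr(x, y, depths=(1, 2))
        assert ours == pytest.approx(ref, abs=0.02)

    def test_marginal_p_gives_positive_fdr(self):
        # construct samples whose full-data p sits just under 0.05
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(0.0, 1.0, 10)
            y = rng.normal(0.0, 1.0, 10)
            _, p = two_sample_p(x, y, "t_eq")
            if 0.03 < p <= 0.05:
                break
        else:
            pytest.skip("no marginal draw found")
        assert leave_k_out_fdr(x, y, depths=(1, 2)) > 0.0

    def test_invalid_depths(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        with pytest.raises(ScreenError):
            leave_k_out_fdr(x, y, depths=(0, 1))
        with pytest.raises(ScreenError):
            leave_k_out_fdr(x, y, depths=(10,))

    def test_invariant_under_within_group_relabeling(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 11)
        f1 = leave_k_out_fdr(x, y, depths=(1,))
        f2 = leave_k_out_fdr(rng.permutation(x), rng.permutation(y), depths=(1,))
        assert f1 == f2

    def test_fdr_zero_when_all_resampled_significant(self, rng):
        x, y = rng.normal(0, 0.2, 12), rng.normal(5, 0.2, 12)
        fdr, ps = leave_k_out_fdr(x, y, depths=(1, 2), return_pvalues=True)
        assert max(ps) <= 0.05
        assert fdr == 0.0


# -- ROC / AUC -----------------------------------------------------------------


class TestRocAuc:
    def test_identical_samples(self, rng):
        x = rng.normal(size=25)
        assert roc_auc(x, x.copy()) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3], [4, 5, 6]) == 1.0
        assert roc_auc([4, 5, 6], [1, 2, 3]) == 1.0

    def test_matches_bruteforce_pair_counting(self, rng):
        x, y = rng.normal(0.5, 1, 30), rng.normal(0, 1, 29)
        brute = np.mean([[(xi > yj) + 0.5 * (xi == yj) for yj in y] for xi in x])
        assert roc_auc(x, y) == pytest.approx(max(brute, 1 - brute), abs=1e-12)

    def test_matches_trapezoidal_roc_integration(self, rng):
        from sklearn.metrics import roc_auc_score

        x = rng.integers(0, 6, 30).astype(float)  # ties exercise the 1/2 credit
        y = rng.integers(0, 6, 29).astype(float)
        labels = np.r_[np.ones(30), np.zeros(29)]
        ref = roc_auc_score(labels, np.r_[x, y])
        assert roc_auc(x, y) == pytest.approx(max(ref, 1 - ref), abs=1e-12)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_always_oriented_above_half(self, xs, ys):
        a = roc_auc(xs, ys)
        assert 0.5 <= a <= 1.0


# -- full screen ---------------------------------------------------------------


class TestRunScreen:
    def test_planted_feature_ranks_first(self, make_cohort, rng):
        cols_case, cols_ctrl = {}, {}
        for i in range(6):
            cols_case[f"null_{i}"] = rng.normal(10, 1, 30)
            cols_ctrl[f"null_{i}"] = rng.normal(10, 1, 29)
        cols_case["hit"] = rng.normal(5, 0.5, 30)
        cols_ctrl["hit"] = rng.normal(10, 1.0, 29)
        m = make_cohort(cols_case, cols_ctrl)
        results = run_screen(m, depths=(1,))
        assert results[0].feature == "hit"
        assert results[0].significant
        assert results[0].ratio == pytest.approx(0.5, abs=0.1)

    def test_constant_feature_degenerate(self, make_cohort, rng):
        m = make_cohort(
            {"flat": np.full(10, 3.0), "ok": rng.normal(1, 0.1, 10)},
            {"flat": np.full(10, 3.0), "ok": rng.normal(2, 0.1, 10)},
        )
        results = {r.feature: r for r in run_screen(m, depths=(1,))}
        assert results["flat"].p == 1.0
        assert results["flat"].auc == 0.5
        assert not results["flat"].significant

    def test_sorted_by_auc_descending(self, small_synthetic):
        from metscreen.cohort import impute_below_detection

        m, _ = small_synthetic
        results = run_screen(
            impute_below_detection(m), depths=(1,), features=[f"met_{i:04d}" for i in range(12)]
        )
        aucs = [r.auc for r in results]
        assert aucs == sorted(aucs, reverse=True)

    def test_joint_rule_consistency(self, small_synthetic):
        from metscreen.cohort import impute_below_detection

        m, _ = small_synthetic
        results = run_screen(
            impute_below_detection(m), depths=(1,), features=[f"met_{i:04d}" for i in range(12)]
        )
        for r in results:
            assert r.significant == (r.p <= 0.05 and r.fdr <= 0.1)
            assert 0.0 <= r.fdr <= 1.0

    def test_binary_feature_uses_chi2(self, small_synthetic):
        m, _ = small_synthetic
        results = run_screen(m, depths=(1,), features=["mthfr_var_1"])
        assert results[0].scenario == "chi2"
        assert math.isnan(results[0].mean_case)
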