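"""Classification, concordance accounting and the statistical tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ldlkit as lk


class TestClassifyNcep:
    @pytest.mark.parametrize(
        "ldl, label",
        [(69.999, "< 70"), (-3, "< 70"), (70, "70 to 99"), (99.9, "70 to 99"),
         (100, "100 to 129"), (160, "160 to 189"), (190, ">= 190"), (500, ">= 190")],
    )
    def test_cutoff_belongs_to_upper_band(self, ldl, label):
        assert lk.classify_ncep(ldl).label == label

    def test_non_finite_rejected(self):
        for bad in (math.nan, math.inf):
            with pytest.raises(ValueError):
                lk.classify_ncep(bad)

    @given(a=st.floats(-50, 400), b=st.floats(-50, 400))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone(self, a, b):
        if a <= b:
            assert lk.classify_ncep(a) <= lk.classify_ncep(b)


class TestConcordanceReport:
    def test_perfect_agreement(self):
        vals = [50.0, 85.0, 110.0, 140.0, 170.0, 200.0]
        tg = [90.0] * 6
        r = lk.concordance_report(vals, vals, tg)
        assert r.overall == (6, 6)
        assert r.under_count == r.over_count == 0

    def test_three_subject_enumeration(self):
        # (est cat, direct cat) = (0,0), (1,0), (0,1) -> 1/3, over 1, under 1
        est = [50.0, 80.0, 50.0]
        direct = [50.0, 50.0, 80.0]
        r = lk.concordance_report(est, direct, [90.0, 150.0, 250.0])
        assert r.overall == (1, 3)
        assert r.over_count == 1 and r.under_count == 1
        assert r.by_estimate_category[0] == (1, 2)
        assert r.by_estimate_category[1] == (0, 1)
        assert r.by_direct_category_n == (2, 1, 0, 0, 0, 0)
        assert [c for _, c, _ in r.by_tg_stratum] == [1, 0, 0, 0]

    def test_printed_rate_formatting(self):
        assert lk.format_rate(4414, 5642) == "78.2"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            lk.concordance_report([1.0], [1.0, 2.0], [90.0, 90.0])

    def test_tg_400_rejected(self):
        with pytest.raises(ValueError, match="400"):
            lk.concordance_report([100.0], [100.0], [400.0])

    def test_partition_identities_fuzz(self):
        """C-by-category, C-by-stratum, overall, under/over all partition T."""
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(1, 60))
            est = rng.uniform(-20, 260, n)
            direct = rng.uniform(0, 260, n)
            tg = rng.uniform(0, 399.9, n)
            r = lk.concordance_report(est, direct, tg)
            c, t = r.overall
            assert sum(ci for ci, _ in r.by_estimate_category) == c
            assert sum(ti for _, ti in r.by_estimate_category) == t == n
            assert sum(r.by_direct_category_n) == t
            assert sum(ci for _, ci, _ in r.by_tg_stratum) == c
            assert sum(ti for _, _, ti in r.by_tg_stratum) == t
            assert r.under_count + r.over_count + c == t


class TestProportionCI:
    def test_truncation(self):
        assert lk.proportion_ci(10, 10) == (pytest.approx(100.0), 100.0)
        assert lk.proportion_ci(0, 10)[0] == 0.0

    def test_wald_hand_computation(self):
        lo, hi = lk.proportion_ci(4414, 5642)
        p = 4414 / 5642
        half = 1.96 * math.sqrt(p * (1 - p) / 5642)
        assert lo == pytest.approx(100 * (p - half))
        assert hi == pytest.approx(100 * (p + half))
        assert (round(lo, 1), round(hi, 1)) == (77.2, 79.3)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            lk.proportion_ci(0, 0)


class TestMcNemarExact:
    def test_worked_examples(self):
        assert lk.mcnemar_exact(5, 1) == pytest.approx(2 * 7 / 64)
        assert lk.mcnemar_exact(10, 0) == pytest.approx(2 * 2**-10)
        assert lk.mcnemar_exact(4, 4) == 1.0

    def test_both_zero_is_warned_convention(self):
        with pytest.warns(UserWarning):
            assert lk.mcnemar_exact(0, 0) == 1.0

    def test_matches_binomial_enumeration_all_small_tables(self):
        """Exact p equals direct enumeration for every table with n <= 12."""
        for n in range(1, 13):
            for n01 in range(n + 1):
                n10 = n - n01
                k = min(n01, n10)
                brute = min(1.0, 2 * sum(math.comb(n, j) for j in range(k + 1)) / 2**n)
                assert lk.mcnemar_exact(n01, n10) == pytest.approx(brute, abs=1e-12)
                assert lk.mcnemar_exact(n01, n10) == lk.mcnemar_exact(n10, n01)

    def test_type_i_error_conservative(self):
        """Under exchangeable paired errors the exact test rejects at <= alpha."""
        rng = np.random.default_rng(17)
        n_sim, n_pairs, rejections = 400, 30, 0
        for _ in range(n_sim):
            a = rng.random(n_pairs) < 0.5
            b = rng.random(n_pairs) < 0.5
            n01 = int((a & ~b).sum())
            n10 = int((~a & b).sum())
            if n01 + n10 and lk.mcnemar_exact(n01, n10) < 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_sim)


class TestWilcoxonSignedRank:
    def test_three_positive_differences(self):
        r = lk.wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])
        assert (r.sp, r.sn) == (6, 0)
        assert r.p_two_sided == pytest.approx(0.25)
        assert r.direction == "positive"

    def test_antisymmetric(self):
        r = lk.wilcoxon_signed_rank([-4, 4], [0, 0])
        assert r.sp == r.sn
        assert r.p_two_sided == 1.0
        assert r.direction == "none"

    def test_rank_sum_identity_and_zero_drop(self):
        r = lk.wilcoxon_signed_rank([1, 2, 2, 5, 5], [1, 1, 1, 1, 9])
        assert r.n_nonzero == 4
        assert r.sp + r.sn == 4 * 5 / 2

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning):
            r = lk.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert r.p_two_sided == 1.0 and r.n_nonzero == 0

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_exact_path_matches_sign_enumeration(self, n):
        """Exact p equals brute-force enumeration over all 2^n sign vectors,
        including tied ranks."""
        rng = np.random.default_rng(n)
        for _ in range(25):
            x = np.round(rng.normal(size=n), 1)
            y = np.round(rng.normal(size=n), 1)
            d = x - y
            d = d[d != 0]
            if d.size == 0:
                continue
            res = lk.wilcoxon_signed_rank(x, y)
            ranks = stats.rankdata(np.abs(d))
            total = ranks.sum()
            wmin = min(res.sp, res.sn)
            hits = sum(
                1
                for signs in itertools.product((0, 1), repeat=d.size)
                if (s := sum(r for r, z in zip(ranks, signs) if z)) <= wmin
                or s >= total - wmin
            )
            assert res.exact
            assert res.p_two_sided == pytest.approx(
                min(1.0, hits / 2**d.size), abs=1e-12
            )

    def test_approx_path_agrees_with_scipy(self):
        """Above the exact-enumeration limit the tie-corrected normal
        approximation matches the reference implementation."""
        rng = np.random.default_rng(5)
        x = np.round(rng.normal(size=60), 1)
        y = np.round(x + rng.normal(0.2, 1.0, 60), 1)
        mine = lk.wilcoxon_signed_rank(x, y)
        assert not mine.exact
        ref = stats.wilcoxon(x, y, correction=False, method="approx")
        assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


class TestDifferenceSummary:
    def test_identical_inputs_all_zero(self):
        s = lk.difference_summary([1.0, 2.0], [1.0, 2.0])
        assert s["median"] == 0 and s["iqr"] == (0, 0) and s["p1_p99"] == (0, 0)

    def test_linear_interpolation_quantiles(self):
        s = lk.difference_summary([-2, -1, 0, 1, 2], [0, 0, 0, 0, 0])
        assert s["median"] == 0
        assert s["iqr"] == (-1, 1)  # linear interpolation between order stats

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        direct = rng.normal(100, 20, 50)
        s = lk.difference_summary(direct + 3, direct)
        assert s["median"] == pytest.approx(3)
        assert s["iqr"] == (pytest.approx(3), pytest.approx(3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lk.difference_summary([], [])


class TestMoodMedianTest:
    def test_identical_groups_no_signal(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert lk.mood_median_test([g, g]) == pytest.approx(1.0)

    def test_maximal_separation_fisher(self):
        p = lk.mood_median_test([[1, 1, 1, 1], [9, 9, 9, 9]])
        assert p == pytest.approx(2 / 70)

    def test_matches_scipy_median_test_large_groups(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(loc=m, size=80) for m in (0.0, 0.2, 0.5)]
        mine = lk.mood_median_test(groups)
        _, ref_p, _, _ = stats.median_test(*groups, ties="below", correction=False)
        assert mine == pytest.approx(ref_p)

    def test_type_i_error_near_nominal(self):
        """Three null groups: rejection rate at alpha=.05 within binomial error."""
        rng = np.random.default_rng(8)
        n_sim, rejections = 1000, 0
        for _ in range(n_sim):
            groups = [rng.normal(size=40) for _ in range(3)]
            if lk.mood_median_test(groups) < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_sim)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            lk.mood_median_test([[1.0, 2.0]])


class TestAnovaTamhane:
    def test_identical_groups_share_letter(self):
        g = [1.0, 2.0, 3.0, 2.5]
        r = lk.anova_with_tamhane([g, g, g])
        assert r.f_statistic == pytest.approx(0.0)
        assert len(set(r.letters)) == 1

    def test_two_groups_reduce_to_welch(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 2, 20)
        r = lk.anova_with_tamhane([a, b])
        ref = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert r.pairwise_p[(0, 1)] == pytest.approx(ref)

    def test_published_letter_pattern_all_strata_distinct(self):
        """Simulated VLDL-C:TG groups with the published means/SDs/sizes
        reproduce the published all-distinct letter pattern A-E (every
        stratum's mean differs from every other at these sample sizes)."""
        rng = np.random.default_rng(12)
        means = (0.398, 0.255, 0.197, 0.180, 0.167)
        sds = (0.178, 0.091, 0.055, 0.048, 0.041)
        ns = (499, 2105, 1484, 784, 806)
        groups = [rng.normal(m, s, n) for m, s, n in zip(means, sds, ns)]
        r = lk.anova_with_tamhane(groups)
        assert r.p_omnibus < 0.001
        assert r.letters == ("A", "B", "C", "D", "E")

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(ValueError):
            lk.anova_with_tamhane([[1.0, 1.0], [2.0, 2.0]])


class TestVarianceDecomposition:
    @staticmethod
    def _noiseless_cohort(n=200, seed=2):
        rng = np.random.default_rng(seed)
        panels = []
        for i in range(n):
            tg = rng.uniform(30, 390)
            hdl = rng.uniform(35, 70)
            non_hdl = rng.uniform(90, 220)
            vldl = 0.120 * tg + 0.055 * non_hdl + 2.467
            panels.append(
                lk.LipidPanel(f"s{i}", int(rng.integers(20, 88)), "male",
                              tc=hdl + non_hdl, hdl=hdl, tg=tg,
                              ldl_direct=non_hdl - vldl)
            )
        return panels

    def test_noiseless_exact_recovery(self):
        r = lk.variance_decomposition(self._noiseless_cohort(), ("tg", "non_hdl"))
        assert r.b["tg"] == pytest.approx(0.120, abs=1e-8)
        assert r.b["non_hdl"] == pytest.approx(0.055, abs=1e-8)
        assert r.intercept == pytest.approx(2.467, abs=1e-7)
        assert r.adjusted_r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_predictor_partial_equals_zero_order(self):
        cohort = lk.generate_cohort(lk.SyntheticCohortConfig(n=300, seed=9))
        r = lk.variance_decomposition(cohort, ("tg",))
        assert r.partial_r["tg"] == pytest.approx(r.zero_order_r["tg"])

    def test_partial_r_matches_residual_brute_force(self):
        """Partial correlation for tg on a 5-point hand dataset equals the
        correlation of residuals from two small hand-solved OLS fits."""
        tg = np.array([50.0, 100.0, 150.0, 200.0, 300.0])
        nh = np.array([110.0, 120.0, 150.0, 140.0, 180.0])
        vldl = np.array([10.0, 22.0, 31.0, 38.0, 62.0])
        panels = [
            lk.LipidPanel(f"h{i}", 40, "male", tc=50 + nh[i], hdl=50.0,
                          tg=tg[i], ldl_direct=nh[i] - vldl[i])
            for i in range(5)
        ]
        r = lk.variance_decomposition(panels, ("tg", "non_hdl"))
        # brute force: residuals of vldl ~ nh and tg ~ nh via lstsq
        A = np.vstack([np.ones(5), nh]).T
        res_y = vldl - A @ np.linalg.lstsq(A, vldl, rcond=None)[0]
        res_x = tg - A @ np.linalg.lstsq(A, tg, rcond=None)[0]
        brute = np.corrcoef(res_x, res_y)[0, 1]
        assert r.partial_r["tg"] == pytest.approx(brute)

    def test_adjusted_r2_not_above_r2(self):
        cohort = lk.generate_cohort(lk.SyntheticCohortConfig(n=500, seed=13))
        r = lk.variance_decomposition(cohort, ("tg", "non_hdl", "hdl", "age"))
        assert r.adjusted_r2 <= r.r2
        assert all(-1 <= v <= 1 for v in r.partial_r.values())

    def test_collinear_predictors_named(self):
        panels = self._noiseless_cohort(50)
        # age copies tg exactly -> perfectly collinear pair
        clones = [
            lk.LipidPanel(p.subject_id, int(round(p.tg)), p.sex, tc=p.tc,
                          hdl=p.hdl, tg=float(round(p.tg)), ldl_direct=p.ldl_direct)
            for p in panels
        ]
        with pytest.raises(ValueError, match="tg and age"):
            lk.variance_decomposition(clones, ("tg", "age"))
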