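"""Behavioral statistics: localization, learning curves, Wilcoxon tests, CIs."""

from itertools import combinations

import numpy as np
import pytest

from polyhand import stats as st
from polyhand.errors import DegenerateDataError, InsufficientDataError
from polyhand.recordings import GameSessionLog, LocalizationDataset
from polyhand.synthetic import GameModelSpec, simulate_game, simulate_localization


def make_log(times_min, levels, condition="six_finger"):
    n = len(times_min)
    return GameSessionLog(condition=condition,
                          events=list(zip(map(float, times_min), map(int, levels))),
                          accuracy=[0.6] * n, error_rate=[0.2] * n)


class TestLocalization:
    def test_perfect_reports_zero_error(self):
        data = simulate_localization(n_reps=4, error_sd=0.0, seed=0)
        errs = st.localization_error(data)
        assert errs.overall == 0.0
        assert all(v == 0.0 for v in errs.per_finger.values())

    def test_pythagorean_offset(self):
        true = np.array([1.0, 2.0])
        data = LocalizationDataset(points={("T", "tip"): [(true + [3.0, 4.0], true)]})
        assert st.localization_error(data).overall == pytest.approx(5.0)

    def test_matches_bruteforce_recomputation(self):
        data = simulate_localization(n_reps=5, error_sd=1.3, seed=7)
        errs = st.localization_error(data)
        flat = [np.linalg.norm(rep - true)
                for pairs in data.points.values() for rep, true in pairs]
        assert errs.overall == pytest.approx(np.mean(flat))
        for (finger, lm), pairs in data.points.items():
            expect = np.mean([np.linalg.norm(r - t) for r, t in pairs])
            assert errs.per_landmark[(finger, lm)] == pytest.approx(expect)


class TestLearningSlope:
    def test_unit_slope(self):
        curve = st.learning_slope(make_log([0, 60, 120], [1, 2, 3]))
        assert curve.slope == pytest.approx(1.0)

    def test_constant_level_zero_slope(self):
        assert st.learning_slope(make_log([0, 60, 120], [2, 2, 2])).slope == 0.0

    def test_degenerate_times(self):
        with pytest.raises(DegenerateDataError):
            st.learning_slope(make_log([5, 5, 5], [1, 2, 3]))

    def test_generator_slope_recovered_within_2_se(self):
        spec = GameModelSpec(seed=21, slopes={"six_finger": 2.0, "five_plus_one": 2.0})
        log = simulate_game(spec)["six_finger"]
        curve = st.learning_slope(log)
        t = log.times_min / 60.0
        resid = log.levels - (curve.intercept + curve.slope * t)
        se = np.sqrt(np.sum(resid ** 2) / (len(t) - 2) / np.sum((t - t.mean()) ** 2))
        assert abs(curve.slope - 2.0) < 2 * max(se, 0.2)


class TestBootstrapSlopeDiff:
    def test_identical_noise_free_logs_p_one(self):
        log_a = make_log([0, 60, 120, 180], [1, 2, 3, 4])
        log_b = make_log([0, 60, 120, 180], [1, 2, 3, 4], condition="five_plus_one")
        res = st.bootstrap_slope_diff(log_a, log_b, n_boot=500, seed=0)
        assert res.p == 1.0

    def test_seed_deterministic(self):
        logs = simulate_game(GameModelSpec(seed=5))
        r1 = st.bootstrap_slope_diff(logs["six_finger"], logs["five_plus_one"],
                                     n_boot=1000, seed=42)
        r2 = st.bootstrap_slope_diff(logs["six_finger"], logs["five_plus_one"],
                                     n_boot=1000, seed=42)
        assert r1.p == r2.p and r1.ci == r2.ci

    def test_separated_slopes_rejected(self):
        logs = simulate_game(GameModelSpec(seed=3, slopes={"a": 1.0, "b": 3.0},
                                           noise_sd=0.3))
        res = st.bootstrap_slope_diff(logs["a"], logs["b"], n_boot=2000, seed=9)
        assert res.p < 0.01
        assert res.statistic < 0  # a minus b


def enumeration_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:n1].sum()
    ws = [ranks[list(idx)].sum() for idx in combinations(range(n), n1)]
    ws = np.array(ws)
    p = 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs))
    return min(1.0, p)


def enumeration_signedrank_p(x, y):
    """Exact two-sided signed-rank p by enumeration of all sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    totals = []
    for bits in range(2 ** n):
        signs = [(bits >> i) & 1 for i in range(n)]
        totals.append(sum(r for r, s in zip(ranks, signs) if s))
    totals = np.array(totals)
    p = 2 * min(np.mean(totals <= w_obs), np.mean(totals >= w_obs))
    return min(1.0, p)


class TestWilcoxon:
    def test_extreme_allocation_exact_p(self):
        res = st.wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0, 5.0])
        assert res.p == pytest.approx(0.2)
        assert res.statistic == 3.0  # ranks 1 + 2

    def test_identical_single_values_p_one(self):
        res = st.wilcoxon_ranksum([2.0], [2.0])
        assert res.p == pytest.approx(1.0)

    def test_exact_equals_enumeration_all_small_instances(self, rng):
        for n1 in range(1, 8):
            for n2 in range(1, 8 - n1 + 1):
                for _ in range(3):
                    x = rng.standard_normal(n1)
                    y = rng.standard_normal(n2)
                    res = st.wilcoxon_ranksum(x, y)
                    assert res.p == pytest.approx(enumeration_ranksum_p(x, y),
                                                  abs=1e-12), (n1, n2)

    def test_exact_and_asymptotic_branches_close(self, rng):
        diffs = []
        for _ in range(20):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6) + 0.5
            exact = st.wilcoxon_ranksum(x, y).p
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True).pvalue
            diffs.append(abs(exact - approx))
        assert max(diffs) < 0.02

    def test_signedrank_shift_by_one_n2(self):
        x = np.array([1.0, 2.0])
        res = st.wilcoxon_signedrank(x, x + 1.0)
        assert res.p == pytest.approx(0.5)

    def test_signedrank_identical_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero"):
            res = st.wilcoxon_signedrank(x, x.copy())
        assert res.p == 1.0

    def test_signedrank_swap_symmetry(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        assert st.wilcoxon_signedrank(x, y).p == pytest.approx(
            st.wilcoxon_signedrank(y, x).p)

    def test_signedrank_exact_equals_enumeration(self, rng):
        for n in range(2, 9):
            for _ in range(3):
                x = rng.standard_normal(n)
                y = rng.standard_normal(n)
                res = st.wilcoxon_signedrank(x, y)
                assert res.p == pytest.approx(enumeration_signedrank_p(x, y),
                                              abs=1e-12), n


class TestMeanDiffCI:
    def test_degenerate_paired_interval(self):
        x = np.array([2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="zero variance"):
            ci = st.mean_diff_ci(x, x, paired=True)
        assert ci == (0.0, 0.0)

    def test_two_sample_textbook_formula(self, rng):
        from scipy.stats import t as t_dist

        x = rng.standard_normal(12) + 1.0
        y = rng.standard_normal(9)
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
        half = t_dist.ppf(0.975, nx + ny - 2) * np.sqrt(sp2 * (1 / nx + 1 / ny))
        expect = (x.mean() - y.mean() - half, x.mean() - y.mean() + half)
        got = st.mean_diff_ci(x, y, paired=False)
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_interval_widens_with_level(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        lo95, hi95 = st.mean_diff_ci(x, y, paired=False, level=0.95)
        lo99, hi99 = st.mean_diff_ci(x, y, paired=False, level=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_six_minus_five_sign_convention(self):
        six = np.array([10.0, 11.0, 12.0])
        five = np.array([1.0, 2.0, 3.0])
        lo, hi = st.mean_diff_ci(six, five, paired=False)
        assert lo > 0  # larger six-fingered mean -> positive interval

    def test_insufficient_n(self):
        with pytest.raises(InsufficientDataError):
            st.mean_diff_ci([1.0], [2.0, 3.0], paired=False)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert st.pearson(x, 2 * x + 3) == pytest.approx(1.0)
        assert st.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        expect = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert st.pearson(x, y) == pytest.approx(expect, abs=1e-12)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDataError):
            st.pearson(np.ones(5), np.arange(5.0))
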