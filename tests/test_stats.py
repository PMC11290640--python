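"""Unit and property tests for the two-sample test kernels, correlations,
and linear/robust fits, cross-checked against scipy/statsmodels and against
brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxscreen.stats import (
    DegenerateComparisonError,
    correlation,
    huber_fit,
    linear_fit,
    mann_whitney_test,
    mood_median_test,
    welch_t_test,
)

ints_list = st.lists(st.integers(-1000, 1000), min_size=4, max_size=30)


# ---------------------------------------------------------------------------
# Welch t


class TestWelch:
    def test_identical_groups_give_zero_statistic(self):
        r = welch_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_hand_computed_example(self):
        # both groups have s^2 = 2.5, so t = -1 with df = 8
        r = welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.statistic == pytest.approx(-1.0)
        assert r.p == pytest.approx(2 * sps.t.sf(1.0, 8), rel=1e-12)
        assert r.p == pytest.approx(0.3466, abs=1e-4)

    def test_group_swap_symmetry(self, rng):
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.p == pytest.approx(b.p) and a.statistic == pytest.approx(-b.statistic)

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(3, 40))
            y = rng.normal(0.3, 1.7, rng.integers(3, 40))
            ours = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_both_constant_unequal_is_degenerate(self):
        with pytest.raises(DegenerateComparisonError):
            welch_t_test([1, 1, 1], [2, 2, 2])


# ---------------------------------------------------------------------------
# Mann-Whitney


def _brute_force_mwu_p(x, y):
    """Two-sided exact p by enumerating all C(n1+n2, n1) label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = sps.rankdata(pooled)[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestMannWhitney:
    def test_small_separated_groups_exact_third(self):
        r = mann_whitney_test([1, 2], [3, 4])
        assert r.statistic == 0.0 and r.p == pytest.approx(1 / 3)

    def test_identical_multisets_with_ties(self):
        r = mann_whitney_test([1, 1, 2, 3], [1, 1, 2, 3])
        assert r.p >= 0.99

    def test_exact_p_equals_brute_force_enumeration(self, rng):
        # the distribution-counting recurrence against raw enumeration
        for _ in range(200):
            n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
            x = rng.normal(0, 1, n1)
            y = rng.normal(rng.uniform(-1, 1), 1, n2)
            ours = mann_whitney_test(x, y)
            assert ours.p == pytest.approx(_brute_force_mwu_p(x, y), rel=1e-10)

    def test_exact_matches_scipy_exact(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0.8, 1, 15)
            ours = mann_whitney_test(x, y)
            ref = sps.mannwhitneyu(x, y, method="exact")
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_large_sample_path_close_to_exact(self, rng):
        x = rng.normal(0, 1, 60)  # > 50 forces the normal approximation
        y = rng.normal(0.4, 1, 60)
        ours = mann_whitney_test(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(ints_list, ints_list)
    def test_monotone_transform_invariance(self, x, y):
        r1 = mann_whitney_test(x, y)
        f = lambda v: np.exp(np.asarray(v, dtype=float) / 500.0)  # strictly increasing
        r2 = mann_whitney_test(f(x), f(y))
        assert r1.p == pytest.approx(r2.p, rel=1e-9)


# ---------------------------------------------------------------------------
# Mood median


class TestMoodMedian:
    def test_fully_separated_small_groups(self):
        # table [[0,3],[3,0]]: chi2 = n(ad-bc)^2 / (row x col products) = 6
        r = mood_median_test([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(6.0)
        assert r.p == pytest.approx(sps.chi2.sf(6.0, 1), rel=1e-12)
        assert r.p == pytest.approx(0.0143, abs=1e-3)

    def test_identical_groups(self):
        r = mood_median_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_all_equal_is_degenerate(self):
        r = mood_median_test([5, 5], [5, 5])
        assert r.degenerate and r.p == 1.0

    def test_matches_scipy_median_test(self, rng):
        # scipy's ties='below' matches the "at or below the median" convention
        for _ in range(20):
            x = rng.normal(0, 1, 21)
            y = rng.normal(0.7, 1, 17)
            ours = mood_median_test(x, y)
            stat, p, _, _ = sps.median_test(x, y, ties="below", correction=False)
            assert ours.p == pytest.approx(p, rel=1e-9)

    def test_yates_correction_shrinks_statistic(self):
        plain = mood_median_test([1, 2, 3], [4, 5, 6])
        corrected = mood_median_test([1, 2, 3], [4, 5, 6], yates=True)
        assert corrected.statistic < plain.statistic

    def test_exact_level_matches_hypergeometric_enumeration(self, rng):
        """At n=50/50 the 2x2 margins are fixed, so the uncorrected test's
        true level is exactly computable: ~0.0713 at alpha=0.05.  The
        simulated rejection rate must match that enumeration, not 0.05."""
        rv = sps.hypergeom(100, 50, 50)
        exact_level = sum(
            rv.pmf(k)
            for k in range(51)
            if sps.chi2.sf(0.16 * (k - 25) ** 2, 1) < 0.05
        )
        assert exact_level == pytest.approx(0.0713, abs=5e-4)
        n_rep = 2000
        hits = sum(
            mood_median_test(rng.normal(0, 1, 50), rng.normal(0, 1, 50)).p < 0.05
            for _ in range(n_rep)
        )
        se = np.sqrt(exact_level * (1 - exact_level) / n_rep)
        assert abs(hits / n_rep - exact_level) < 4 * se


# ---------------------------------------------------------------------------
# shared label-permutation symmetry


@pytest.mark.parametrize("test_fn", [welch_t_test, mann_whitney_test, mood_median_test])
def test_label_swap_leaves_p_unchanged(test_fn, rng):
    for _ in range(10):
        x = rng.normal(0, 1, rng.integers(4, 20))
        y = rng.normal(0.5, 1.5, rng.integers(4, 20))
        assert test_fn(x, y).p == pytest.approx(test_fn(y, x).p, rel=1e-9)


# ---------------------------------------------------------------------------
# correlations and fits


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2, 3, 5])
        for m in ("pearson", "spearman", "kendall"):
            assert correlation(x, 3 * x + 2, m) == pytest.approx(1.0)
            assert correlation(x, -x, m) == pytest.approx(-1.0)

    def test_kendall_concordance_enumeration(self):
        # pairs (1,2),(2,1),(3,3): 2 concordant, 1 discordant -> tau = 1/3
        assert correlation([1, 2, 3], [2, 1, 3], "kendall") == pytest.approx(1 / 3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1], [1, 2, 3], "pearson")

    def test_monotone_cubic_is_rank_perfect(self):
        x = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        y = x**3
        assert correlation(x, y, "spearman") == pytest.approx(1.0)
        assert correlation(x, y, "kendall") == pytest.approx(1.0)
        assert correlation(x, y, "pearson") < 1.0


class TestFits:
    def test_exact_line_recovered_by_both(self):
        x = np.arange(10.0)
        y = 2 + 3 * x
        for fit in (linear_fit, huber_fit):
            res = fit(x, y)
            assert res.slope == pytest.approx(3.0, abs=1e-6)
            assert res.intercept == pytest.approx(2.0, abs=1e-6)

    def test_huber_downweights_outlier(self):
        x = np.arange(20.0)
        y = x.copy()
        x = np.append(x, 10.0)
        y = np.append(y, 100.0)
        lm, rlm = linear_fit(x, y), huber_fit(x, y)
        assert abs(rlm.slope - 1.0) < abs(lm.slope - 1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1, 1, 1], [1, 2, 3])
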