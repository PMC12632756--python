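"""Rank tests against full enumeration, BH, letters, effect sizes, fences."""

from itertools import combinations, product

import numpy as np
import pytest

from socialetho.core import ValidationError
from socialetho.stats import (
    StatsParams,
    assign_letters,
    bh_adjust,
    binomial_tests,
    cohens_d,
    kruskal_dunn,
    ks_two_sample,
    mann_whitney,
    pearson_linfit,
    tukey_outliers,
)

# ---------------------------------------------------------------------------
# independent enumeration oracles


def exact_mw_p(x, y):
    """Two-sided Mann-Whitney p by enumerating all rank splits (no ties)."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}

    def u_of(xs):
        r = sum(ranks[v] for v in xs)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(x)
    mean_u = n1 * len(y) / 2
    stat_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for subset in combinations(pooled, n1):
        u = u_of(subset)
        total += 1
        if abs(u - mean_u) >= stat_obs - 1e-12:
            count += 1
    return count / total


def exact_signed_rank_p(d):
    """Two-sided Wilcoxon signed-rank p by enumerating all sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    stat_obs = abs(w_obs - mean_w)
    count = 0
    for signs in product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / 2 ** len(d)


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 * 1/20

    def test_one_sample_all_positive(self):
        res = mann_whitney([1, 2, 3], null_median=0.0)
        assert res.p_value == pytest.approx(0.25)  # 2 * 1/8

    def test_paired_degenerate(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0], paired=True)
        assert res.degenerate

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([1, 2], [1, 2, 3], paired=True)

    def test_exact_p_matches_enumeration(self, rng):
        """Property: exact p-values equal brute-force enumeration over all
        rank splits for combined n <= 10 (continuous data, no ties)."""
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney(x, y)
            assert "exact" in res.method
            assert res.p_value == pytest.approx(exact_mw_p(list(x), list(y)))

    def test_signed_rank_matches_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 11))
            x = rng.normal(loc=0.3, size=n)
            res = mann_whitney(x, null_median=0.0)
            assert res.p_value == pytest.approx(exact_signed_rank_p(x))

    def test_large_n_uses_normal_approximation(self, rng):
        res = mann_whitney(rng.normal(size=30), rng.normal(size=30))
        assert "approx" in res.method


class TestKS:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_ecdfs(self):
        assert ks_two_sample([1, 2], [3, 4]).statistic == 1.0

    def test_interleaved(self):
        assert ks_two_sample([1, 3], [2, 4]).statistic == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])


class TestKruskalDunn:
    def test_identical_groups_all_share_letter(self):
        g = [1.0, 2.0, 3.0, 4.0]
        omni, pairwise, letters = kruskal_dunn([g, g, g])
        assert omni.statistic == pytest.approx(0.0)
        assert all(d["p_adj"] > 0.9 for d in pairwise)
        assert letters == ["a", "a", "a"]

    def test_hand_rank_z_formula(self):
        """z for the separated group checked against the tie-corrected
        formula computed by hand."""
        groups = [[1, 2, 3], [1, 2, 3], [101, 102, 103]]
        _, pairwise, letters = kruskal_dunn(groups)
        by_pair = {(d["i"], d["j"]): d for d in pairwise}
        # pooled ranks: ties across groups 1,2 -> mean rank 3.5 each; group 3 -> 8
        # T = 3 tie groups of 2 -> sum(t^3 - t) = 18
        se = np.sqrt((9 * 10 / 12 - 18 / (12 * 8)) * (1 / 3 + 1 / 3))
        z_expected = (3.5 - 8.0) / se
        assert by_pair[(0, 2)]["z"] == pytest.approx(z_expected)
        assert by_pair[(0, 1)]["z"] == pytest.approx(0.0)
        assert by_pair[(0, 1)]["p_adj"] > 0.9
        assert letters[0] == letters[1]  # non-separated groups share a letter

    def test_clearly_separated_letters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, 30)
        b = rng.normal(0, 0.1, 30)
        c = rng.normal(10, 0.1, 30)
        _, _, letters = kruskal_dunn([a, b, c])
        assert letters == ["a", "a", "b"]

    def test_two_groups_bh_identity(self):
        _, pairwise, _ = kruskal_dunn([[1, 2, 3], [4, 5, 6]])
        assert len(pairwise) == 1
        assert pairwise[0]["p_adj"] == pytest.approx(pairwise[0]["p"])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_dunn([[1, 2, 3]])


class TestAssignLetters:
    def test_none_significant(self):
        assert assign_letters(np.zeros((3, 3), bool)) == ["a", "a", "a"]

    def test_all_significant(self):
        assert assign_letters(~np.eye(3, dtype=bool)) == ["a", "b", "c"]

    def test_one_group_separated(self):
        sig = np.zeros((3, 3), bool)
        sig[0, 2] = sig[2, 0] = sig[1, 2] = sig[2, 1] = True
        assert assign_letters(sig) == ["a", "a", "b"]

    def test_asymmetric_rejected(self):
        sig = np.zeros((2, 2), bool)
        sig[0, 1] = True
        with pytest.raises(ValidationError):
            assign_letters(sig)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_letter_sharing_complements_significance_exhaustively(self, k):
        """Over every possible significance pattern on k groups, two groups
        share a letter iff they are not significantly different."""
        pairs = list(combinations(range(k), 2))
        for bits in product([False, True], repeat=len(pairs)):
            sig = np.zeros((k, k), bool)
            for (i, j), b in zip(pairs, bits):
                sig[i, j] = sig[j, i] = b
            letters = assign_letters(sig)
            for i, j in pairs:
                share = bool(set(letters[i]) & set(letters[j]))
                assert share == (not sig[i, j]), (bits, letters)


class TestBinomial:
    def test_all_successes_two_sided(self):
        assert binomial_tests(9, 9, p0=0.5).p_value == pytest.approx(0.00390625)

    def test_exact_null_probability_gives_one(self):
        assert binomial_tests(5, 10, p0=0.5).p_value == pytest.approx(1.0)

    def test_balanced_two_sample(self):
        assert binomial_tests(5, 10, k2=5, n2=10).p_value == pytest.approx(1.0)

    def test_ztest_mode_runs(self):
        res = binomial_tests(40, 50, k2=10, n2=50, mode="ztest")
        assert res.p_value < 1e-6

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            binomial_tests(5, 3, p0=0.5)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(bh_adjust([0.04, 0.5]), [0.08, 0.5])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_monotone_and_not_below_input(self, rng):
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).statistic == 0.0

    def test_unit_pooled_sd(self):
        res = cohens_d([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.0)
        assert res.extra["ci_low"] < -1.0 < res.extra["ci_high"]

    def test_location_shift(self):
        x = np.array([0.0, 2.0, 4.0, 6.0])
        res = cohens_d(x, x + 3.0)
        sd = x.std(ddof=1)
        assert res.statistic == pytest.approx(-3.0 / sd)

    def test_zero_pooled_sd_flagged(self):
        assert cohens_d([2, 2, 2], [2, 2, 2]).degenerate


class TestTukeyOutliers:
    def test_flags_extreme_only(self):
        flags = tukey_outliers([1, 2, 3, 4, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_vector_no_flags(self):
        assert not tukey_outliers([5.0] * 6).any()

    def test_symmetric_within_fences(self):
        assert not tukey_outliers([-2, -1, 0, 1, 2]).any()

    def test_small_n_no_flags(self):
        assert not tukey_outliers([1, 100, 1000]).any()

    def test_flags_never_remove(self):
        x = [1, 2, 3, 4, 100]
        flags = tukey_outliers(x)
        assert len(flags) == len(x)


class TestPearsonLinfit:
    def test_exact_line(self):
        res = pearson_linfit([0, 1, 2, 3], [1, 3, 5, 7])
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["r"] == pytest.approx(1.0)

    def test_hand_normal_equations(self):
        res = pearson_linfit([0, 1, 2], [0, 1, 3])
        assert res["slope"] == pytest.approx(1.5)
        assert res["intercept"] == pytest.approx(-1 / 6)

    def test_constant_y_degenerate(self):
        res = pearson_linfit([0, 1, 2], [5, 5, 5])
        assert res["degenerate"] and res["r"] == 0.0

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_linfit([1, 1, 1], [1, 2, 3])


def test_type_one_error_calibration(rng):
    """Null rejection rate of the two-sample rank test at alpha = 0.05 stays
    near nominal (n = 10 per group, 500 replicates here; the acceptance
    suite runs the full 2,000)."""
    rejections = 0
    reps = 500
    for _ in range(reps):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        if mann_whitney(x, y).p_value < 0.05:
            rejections += 1
    assert 0.02 <= rejections / reps <= 0.08
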