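"""Kernel tests: worked examples frozen from independent oracles, plus
property checks against brute-force enumeration and reference libraries."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from slscreen.stats import (
    bh_fdr,
    hypergeom_tail,
    rank_sum_test,
    spearman_test,
    welch_t_test,
)

# ---------------------------------------------------------------------------
# independent oracles (kept free of slscreen internals)


def ranksum_enumeration_p(a, b, alternative):
    """Exhaustive rank-assignment oracle for the rank-sum test."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, n_a = len(pooled), len(a)
    observed = ranks[:n_a].sum()
    sums = [sum(ranks[i] for i in idx) for idx in combinations(range(n), n_a)]
    eps = 1e-9
    less = np.mean([s <= observed + eps for s in sums])
    greater = np.mean([s >= observed - eps for s in sums])
    if alternative == "less":
        return less
    if alternative == "greater":
        return greater
    return min(1.0, 2 * min(less, greater))


def spearman_enumeration_p(x, y, alternative):
    """Full-permutation oracle using scipy's rho implementation."""
    rho_obs = sps.spearmanr(x, y).statistic
    eps = 1e-12
    n_ge = n_le = n_abs = 0
    total = 0
    for perm in permutations(y):
        r = sps.spearmanr(x, perm).statistic
        n_ge += r >= rho_obs - eps
        n_le += r <= rho_obs + eps
        n_abs += abs(r) >= abs(rho_obs) - eps
        total += 1
    if alternative == "greater":
        return n_ge / total
    if alternative == "less":
        return n_le / total
    return min(1.0, n_abs / total)


# ---------------------------------------------------------------------------
# worked examples


@pytest.mark.parametrize(
    "a, b, alternative, expected_p",
    [
        ([1, 2], [3, 4], "less", 1 / 6),
        ([1, 2, 3], [4, 5, 6], "less", 1 / 20),
        ([0, 0], [0, 0], "two_sided", 1.0),
        ([0.1, 0.2], [-0.5, -0.6], "greater", 1 / 6),
        ([-2.0, -1.9], [0.0, 0.1], "less", 1 / 6),
        # swapped groups: inclusive convention gives P(W <= max) = 1
        ([0.0, 0.1], [-2.0, -1.9], "less", 1.0),
        ([0.0, 0.1], [-2.0, -1.9], "greater", 1 / 6),
    ],
)
def test_rank_sum_worked_examples(a, b, alternative, expected_p):
    res = rank_sum_test(a, b, alternative)
    assert res.p_value == pytest.approx(expected_p, rel=1e-6)


def test_rank_sum_statistic_is_rank_sum_of_a():
    res = rank_sum_test([10.0, 20.0], [1.0, 2.0], "greater")
    assert res.statistic == 3 + 4  # a holds the top two ranks


def test_rank_sum_rejects_empty_group():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0], "less")


def test_welch_worked_example():
    res = welch_t_test([1, 2, 3, 4], [5, 6, 7, 8])
    # closed form: diff -4, se = sqrt(2 * (5/3) / 4), df = 6
    se = math.sqrt(2 * (5 / 3) / 4)
    t_expected = -4 / se
    p_expected = 2 * sps.t.cdf(t_expected, df=6)
    assert res.statistic == pytest.approx(t_expected, rel=1e-6)
    assert res.p_value == pytest.approx(p_expected, rel=1e-6)
    assert res.p_value == pytest.approx(0.0047, abs=5e-4)


def test_welch_identical_groups():
    res = welch_t_test([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_welch_degenerate_zero_variance():
    res = welch_t_test([1, 1, 1], [2, 2, 2])
    assert res.degenerate and res.p_value == 0.0 and res.statistic < 0


def test_welch_requires_two_per_group():
    with pytest.raises(ValueError):
        welch_t_test([1.0], [1.0, 2.0])


def test_spearman_worked_examples():
    assert spearman_test([1, 2, 3], [1, 2, 3]).statistic == pytest.approx(1.0)
    res = spearman_test([1, 2, 3, 4, 5], [1, 3, 2, 4, 5], "greater")
    assert res.statistic == pytest.approx(0.9, rel=1e-6)
    assert res.p_value == pytest.approx(5 / 120, rel=1e-6)


def test_spearman_drops_missing_pairs_and_needs_three():
    res = spearman_test([1, 2, 3, np.nan], [1, 2, 3, 4])
    assert res.n_a == 3
    with pytest.raises(ValueError):
        spearman_test([1, np.nan, 3], [1, 2, 3])


def test_spearman_zero_variance_flagged():
    res = spearman_test([1, 1, 1, 1], [1, 2, 3, 4])
    assert res.degenerate and math.isnan(res.statistic)


@pytest.mark.parametrize(
    "N, K, n, k, expected",
    [
        (20, 5, 5, 5, 1 / 15504),
        (10, 5, 5, 4, 26 / 252),
        (33, 7, 12, 0, 1.0),
    ],
)
def test_hypergeom_worked_examples(N, K, n, k, expected):
    assert hypergeom_tail(N, K, n, k) == pytest.approx(expected, rel=1e-6)


def test_hypergeom_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeom_tail(10, 5, 5, 6)
    with pytest.raises(ValueError):
        hypergeom_tail(10, 12, 5, 3)


@pytest.mark.parametrize(
    "p, expected_q",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.005, 0.5], [0.01, 0.5]),
    ],
)
def test_bh_worked_examples(p, expected_q):
    np.testing.assert_allclose(bh_fdr(p), expected_q, rtol=1e-6)


def test_bh_propagates_missing_and_rejects_out_of_range():
    q = bh_fdr([0.01, np.nan, 0.5])
    assert math.isnan(q[1]) and not math.isnan(q[0])
    with pytest.raises(ValueError):
        bh_fdr([1.5])


# ---------------------------------------------------------------------------
# oracle-equivalence properties


@pytest.mark.parametrize(
    "n_a, n_b",
    [(i, j) for i in range(1, 8) for j in range(1, 8) if i + j <= 8],
)
def test_rank_sum_exact_matches_enumeration(n_a, n_b):
    """Exact p equals the brute-force rank-assignment oracle for every group
    size with n_a + n_b <= 8, on untied and heavily tied data."""
    rng = np.random.default_rng(1000 * n_a + n_b)
    for _ in range(4):
        untied = rng.normal(size=n_a + n_b)
        tied = rng.integers(0, 3, size=n_a + n_b).astype(float)
        for values in (untied, tied):
            a, b = values[:n_a], values[n_a:]
            for alt in ("less", "greater", "two_sided"):
                res = rank_sum_test(a, b, alt)
                assert res.method == "rank_sum_exact"
                assert res.p_value == pytest.approx(
                    ranksum_enumeration_p(a, b, alt), rel=1e-9
                )


def test_rank_sum_exact_matches_scipy_on_untied_data():
    """Cross-check against scipy's exact Mann-Whitney distribution."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        n_a, n_b = rng.integers(2, 6, size=2)
        a = rng.normal(size=n_a)
        b = rng.normal(size=n_b)
        for alt, scipy_alt in (("less", "less"), ("greater", "greater"),
                               ("two_sided", "two-sided")):
            ours = rank_sum_test(a, b, alt)
            ref = sps.mannwhitneyu(a, b, alternative=scipy_alt,
                                   method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_rank_sum_normal_approximation_close_to_exact():
    """Tie-corrected normal p within 0.02 of the exact p, 5 <= n <= 10."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(1000):
        n_a, n_b = rng.integers(5, 11, size=2)
        a = rng.normal(size=n_a)
        b = rng.normal(loc=rng.normal(), size=n_b)
        approx = rank_sum_test(a, b, "two_sided", exact_limit=0)
        assert approx.method == "rank_sum_normal"
        exact = sps.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact")
        worst = max(worst, abs(approx.p_value - exact.pvalue))
    assert worst < 0.02


@pytest.mark.parametrize("n", [4, 5, 6])
def test_spearman_exact_matches_enumeration(n):
    rng = np.random.default_rng(n)
    for _ in range(3):
        x = rng.permutation(n).astype(float)
        y = rng.normal(size=n)
        for alt in ("less", "greater", "two_sided"):
            res = spearman_test(x, y, alt)
            assert res.method == "spearman_exact"
            assert res.p_value == pytest.approx(
                spearman_enumeration_p(x, y, alt), rel=1e-9
            )


def test_hypergeom_matches_scipy_sf():
    rng = np.random.default_rng(9)
    for _ in range(300):
        N = int(rng.integers(1, 80))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        hi = min(K, n)
        k = int(rng.integers(0, hi + 1)) if hi else 0
        assert hypergeom_tail(N, K, n, k) == pytest.approx(
            sps.hypergeom.sf(k - 1, N, K, n), rel=1e-9, abs=1e-300
        )


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    p = rng.uniform(size=200)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_fdr(p), ref, rtol=1e-12)


# ---------------------------------------------------------------------------
# calibration properties


def test_welch_null_rejection_rate():
    """Under a shared-normal null (n = 20 each), p < 0.05 in [0.03, 0.07]."""
    rng = np.random.default_rng(123)
    hits = 0
    for _ in range(1000):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        hits += welch_t_test(a, b).p_value < 0.05
    assert 0.03 <= hits / 1000 <= 0.07


def test_bh_null_false_discovery_proportion():
    """BH at 0.1 on uniform nulls: mean FDP <= 0.15 over 500 replicates."""
    rng = np.random.default_rng(321)
    fdp = []
    for _ in range(500):
        q = bh_fdr(rng.uniform(size=100))
        fdp.append(1.0 if np.any(q <= 0.1) else 0.0)
    assert np.mean(fdp) <= 0.15


# ---------------------------------------------------------------------------
# invariants (hypothesis)


@given(
    p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
               max_size=50)
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_bh_invariants(p):
    q = bh_fdr(p)
    assert np.all(q >= np.asarray(p) - 1e-12)
    assert np.all(q <= 1.0 + 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


@given(
    a=st.lists(st.floats(min_value=-50, max_value=50,
                         allow_nan=False), min_size=1, max_size=5),
    b=st.lists(st.floats(min_value=-50, max_value=50,
                         allow_nan=False), min_size=1, max_size=5),
    alt=st.sampled_from(["less", "greater", "two_sided"]),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_rank_sum_exact_property(a, b, alt):
    res = rank_sum_test(a, b, alt)
    assert res.p_value == pytest.approx(
        ranksum_enumeration_p(np.asarray(a), np.asarray(b), alt), rel=1e-9
    )


def test_rank_sum_one_sided_complement_on_untied_data():
    rng = np.random.default_rng(77)
    a = rng.normal(size=4)
    b = rng.normal(size=4)
    # P(W <= w) + P(W >= w) = 1 + P(W == w) for the discrete null
    less = rank_sum_test(a, b, "less").p_value
    greater = rank_sum_test(a, b, "greater").p_value
    assert less + greater >= 1.0
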