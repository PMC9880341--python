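"""Statistical kernels shared by every screening workflow.

Five primitives: the one-sided/two-sided Wilcoxon rank-sum test (exact by
enumeration for small samples, tie-corrected normal approximation otherwise),
Welch's unequal-variance t-test, the Spearman rank-correlation test (exact by
permutation enumeration for small n), the upper hypergeometric tail, and
Benjamini-Hochberg step-up q-values.

Conventions
-----------
* ``alternative`` always describes the location of the *first* argument
  relative to the second: ``"less"`` means "a is stochastically smaller than
  b" (or rho < 0 for Spearman).
* Ties are ranked with average ranks throughout.
* Exact paths are taken when the total sample size is at or below a
  configurable ``exact_limit`` (rank-sum: total <= 10; Spearman: n <= 7 and
  no ties), bounding worst-case enumeration cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as _sps
from scipy.special import gammaln, logsumexp

__all__ = [
    "TestResult",
    "rank_sum_test",
    "welch_t_test",
    "spearman_test",
    "hypergeom_tail",
    "bh_fdr",
]

_ALTERNATIVES = ("less", "greater", "two_sided")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``degenerate`` marks results produced from inputs where the sampling
    distribution collapses (e.g. both groups constant with unequal means, or
    a zero-variance vector in a correlation): the p-value is then a
    convention, not an estimate, and downstream screens treat it with care.
    """

    statistic: float
    p_value: float
    method: str
    alternative: str
    n_a: int
    n_b: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _check_alternative(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}"
        )
    return alternative


def _as_finite_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def rank_sum_test(
    a, b, alternative: str = "two_sided", exact_limit: int = 10
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of location.

    The statistic is the rank-sum of ``a`` in the pooled average-ranked
    sample.  When ``len(a) + len(b) <= exact_limit`` the p-value is exact:
    every C(n, n_a) assignment of the pooled ranks to group a is enumerated
    (ties handled naturally because ranks are averaged before enumeration).
    Larger samples use the tie-corrected normal approximation with a
    0.5 continuity correction.
    """
    alternative = _check_alternative(alternative)
    a = _as_finite_1d(a, "a")
    b = _as_finite_1d(b, "b")
    n_a, n_b = a.size, b.size
    n = n_a + n_b

    pooled = np.concatenate([a, b])
    ranks = _sps.rankdata(pooled, method="average")
    w = float(ranks[:n_a].sum())

    if n <= exact_limit:
        sums = np.fromiter(
            (ranks[list(idx)].sum() for idx in combinations(range(n), n_a)),
            dtype=float,
            count=math.comb(n, n_a),
        )
        eps = 1e-9
        p_less = float(np.mean(sums <= w + eps))
        p_greater = float(np.mean(sums >= w - eps))
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return TestResult(w, p, "rank_sum_exact", alternative, n_a, n_b)

    mean = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation tied: no evidence either way
        return TestResult(w, 1.0, "rank_sum_normal", alternative, n_a, n_b,
                          degenerate=True)
    sd = math.sqrt(var)
    p_less = float(_sps.norm.cdf((w - mean + 0.5) / sd))
    p_greater = float(_sps.norm.sf((w - mean - 0.5) / sd))
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return TestResult(w, p, "rank_sum_normal", alternative, n_a, n_b)


def welch_t_test(a, b, alternative: str = "two_sided") -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    The statistic's sign follows ``mean(a) - mean(b)``.  Zero-variance
    degeneracies are resolved by convention: both groups constant and equal
    gives t = 0, p = 1; both constant but different gives a flagged
    degenerate result with p = 0 (the observed separation is perfect but no
    variance estimate exists).
    """
    alternative = _check_alternative(alternative)
    a = _as_finite_1d(a, "a")
    b = _as_finite_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires at least 2 values per group")

    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    diff = float(np.mean(a) - np.mean(b))
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, "welch_t", alternative, a.size, b.size)
        stat = math.copysign(math.inf, diff)
        if alternative == "two_sided":
            p = 0.0
        elif alternative == "greater":
            p = 0.0 if diff > 0 else 1.0
        else:
            p = 0.0 if diff < 0 else 1.0
        return TestResult(stat, p, "welch_t", alternative, a.size, b.size,
                          degenerate=True)

    scipy_alt = {"less": "less", "greater": "greater",
                 "two_sided": "two-sided"}[alternative]
    res = _sps.ttest_ind(a, b, equal_var=False, alternative=scipy_alt)
    return TestResult(float(res.statistic), float(res.pvalue), "welch_t",
                      alternative, a.size, b.size)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman_test(
    x, y, alternative: str = "two_sided", exact_limit: int = 7
) -> TestResult:
    """Spearman rank correlation with exact small-sample p-values.

    Pairs with a missing member are dropped first.  With ``n <= exact_limit``
    and no ties, the p-value enumerates all n! pairings of the rank vectors;
    otherwise the t approximation with n - 2 degrees of freedom is used.
    A zero-variance vector yields an undefined correlation: the result is
    flagged degenerate with rho = nan and p = 1.
    """
    alternative = _check_alternative(alternative)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"spearman_test needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return TestResult(math.nan, 1.0, "spearman_approx", alternative, n, n,
                          degenerate=True)

    rx = _sps.rankdata(x, method="average")
    ry = _sps.rankdata(y, method="average")
    rho = _spearman_rho(rx, ry)

    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= exact_limit and no_ties:
        eps = 1e-12
        n_ge = n_le = n_abs = 0
        total = math.factorial(n)
        for perm in permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            if r >= rho - eps:
                n_ge += 1
            if r <= rho + eps:
                n_le += 1
            if abs(r) >= abs(rho) - eps:
                n_abs += 1
        if alternative == "greater":
            p = n_ge / total
        elif alternative == "less":
            p = n_le / total
        else:
            p = min(1.0, n_abs / total)
        return TestResult(rho, p, "spearman_exact", alternative, n, n)

    if abs(rho) >= 1.0:  # perfect monotone: t statistic diverges
        rho = math.copysign(1.0, rho)
        p_greater, p_less = (0.0, 1.0) if rho > 0 else (1.0, 0.0)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p_greater = float(_sps.t.sf(t, df=n - 2))
        p_less = float(_sps.t.cdf(t, df=n - 2))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return TestResult(rho, p, "spearman_approx", alternative, n, n)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated items, n: items drawn, k: observed
    overlap.  Summed in log-space for stability at extreme tails.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError(f"K and n must not exceed N (N={N}, K={K}, n={n})")
    if k > K or k > n:
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    hi = min(K, n)
    if k < n - (N - K):  # support starts above k: tail is everything
        return 1.0
    ks = np.arange(k, hi + 1)
    logpmf = (
        _log_comb(K, ks) + _log_comb(N - K, n - ks) - _log_comb(N, n)
    )
    return float(min(1.0, math.exp(logsumexp(logpmf))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    Missing entries (NaN) are allowed and propagate as NaN without entering
    the correction.  Output satisfies q >= p, q <= 1, and monotone
    non-decreasing q along the sorted-p order.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    m = int(finite.sum())
    if m == 0:
        return q
    pv = p[finite]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[finite] = out
    return q
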