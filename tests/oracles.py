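"""Independent brute-force oracles used by the test suite.

Deliberately written with plain loops/enumeration, sharing no code with the
package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def enumerate_assignments(n1: int, n2: int):
    """All distinct splits of pooled indices 0..n1+n2-1 into groups of n1/n2."""
    n = n1 + n2
    for chosen in combinations(range(n), n1):
        rest = tuple(i for i in range(n) if i not in chosen)
        yield chosen, rest


def stat_value(pooled: np.ndarray, g1, g2, statistic: str) -> float:
    a = np.asarray([pooled[i] for i in g1], dtype=float)
    b = np.asarray([pooled[i] for i in g2], dtype=float)
    if statistic == "mean_diff":
        return abs(a.mean() - b.mean())
    if statistic == "median_diff":
        return abs(float(np.median(a)) - float(np.median(b)))
    if statistic == "var_ratio":
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            return float("nan")
        if vb == 0 or va == 0:
            return float("inf")
        r = va / vb
        return max(r, 1 / r)
    raise ValueError(statistic)


def brute_perm_pvalue(x1, x2, statistic: str = "mean_diff") -> float:
    """Exhaustive two-sided permutation p-value with ties counted extreme."""
    x1 = list(x1)
    x2 = list(x2)
    pooled = np.asarray(x1 + x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    obs = stat_value(pooled, range(n1), range(n1, n1 + n2), statistic)
    count = 0
    total = 0
    for g1, g2 in enumerate_assignments(n1, n2):
        total += 1
        if stat_value(pooled, g1, g2, statistic) >= obs:
            count += 1
    return count / total


def brute_itp_adjusted(
    X1: np.ndarray, X2: np.ndarray, statistic: str = "mean_diff",
    combining: str = "fisher",
) -> np.ndarray:
    """Exhaustive-enumeration A(L, k) matrix, independent of the package.

    For every assignment the per-component statistic is computed; partial
    p-values are obtained by counting; each contiguous interval is combined
    (Fisher: sum of -2 log p; Tippett: min p) and its p-value counted over
    assignments; A(L, k) is the max over all intervals of length <= L that
    contain k.
    """
    X1 = np.atleast_2d(np.asarray(X1, float))
    X2 = np.atleast_2d(np.asarray(X2, float))
    n1, K = X1.shape
    n2 = X2.shape[0]
    pooled = np.vstack([X1, X2])
    assignments = list(enumerate_assignments(n1, n2))
    B = len(assignments)

    stat = np.empty((B, K))
    for b, (g1, g2) in enumerate(assignments):
        for k in range(K):
            stat[b, k] = stat_value(pooled[:, k], g1, g2, statistic)
    obs = stat[0]  # first assignment is the identity (combinations order)
    assert assignments[0][0] == tuple(range(n1))

    partial = np.empty((B, K))
    for b in range(B):
        for k in range(K):
            partial[b, k] = np.sum(stat[:, k] >= stat[b, k]) / B

    # p-value of every contiguous interval [a, e] (0-based, inclusive)
    interval_p: dict[tuple[int, int], float] = {}
    for a in range(K):
        for e in range(a, K):
            if combining == "fisher":
                scores = np.array(
                    [-2 * np.sum(np.log(partial[b, a : e + 1])) for b in range(B)]
                )
                interval_p[(a, e)] = np.sum(scores >= scores[0]) / B
            else:
                scores = np.array([partial[b, a : e + 1].min() for b in range(B)])
                interval_p[(a, e)] = np.sum(scores <= scores[0]) / B

    A = np.empty((K, K))
    for L in range(1, K + 1):
        for k in range(K):
            ps = [
                p
                for (a, e), p in interval_p.items()
                if (e - a + 1) <= L and a <= k <= e
            ]
            A[L - 1, k] = max(ps)
    return A


def per_base_content(track_intervals, window_start: int, window_end: int) -> float:
    """Fraction of window bases covered by >= 1 interval (per-base boolean)."""
    width = window_end - window_start
    covered = np.zeros(width, dtype=bool)
    for s, e in track_intervals:
        lo = max(s, window_start) - window_start
        hi = min(e, window_end) - window_start
        if hi > lo:
            covered[lo:hi] = True
    return covered.sum() / width


def per_base_wa(track_records, window_start: int, window_end: int) -> float:
    """bp-weighted average by per-base accumulation over every record
    covering each base (NaN if no data)."""
    width = window_end - window_start
    total = np.zeros(width)
    weight = np.zeros(width)
    for s, e, v in track_records:
        lo = max(s, window_start) - window_start
        hi = min(e, window_end) - window_start
        if hi > lo:
            total[lo:hi] += v
            weight[lo:hi] += 1.0
    if weight.sum() == 0:
        return float("nan")
    return total.sum() / weight.sum()


def count_starts(track_intervals, window_start: int, window_end: int) -> int:
    return sum(1 for s, _ in track_intervals if window_start <= s < window_end)


def logistic_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    mu = 1 / (1 + np.exp(-np.asarray(eta, float)))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    y = np.asarray(y, float)
    return float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
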