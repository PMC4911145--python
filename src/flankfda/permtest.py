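"""Two-sample permutation tests with synchronized permutation plans.

The same plan (a fixed set of group-label reassignments) can be applied to
many components at once, which is what makes interval-wise combination of
component tests valid downstream.

Conventions
-----------
* "More extreme" is implemented as ``>=`` (ties count as extreme) and the
  identity assignment is a member of the reference set by default, so
  reported p-values are valid (conservative) and never smaller than 1/B.
* All alternatives are two-sided: location statistics are compared through
  their absolute value, the variance ratio through ``max(r, 1/r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

STATISTICS = ("mean_diff", "median_diff", "var_ratio")

#: permutation rows are processed in chunks of this many rows to bound memory
_CHUNK = 512


@dataclass(frozen=True)
class PermConfig:
    """Configuration of a two-sample permutation test.

    Parameters
    ----------
    n_perm : int
        Number of permutations for a sampled plan (ignored when the plan
        is exhaustive). Must be >= 100 for reported p-values.
    statistics : tuple of str
        Subset of :data:`STATISTICS`.
    seed : int
        Seed for the sampled plan.
    include_observed : bool
        Include the identity assignment in the reference set.
    exhaustive_max_n : int
        Use an exhaustive plan whenever ``n1 + n2`` does not exceed this.
    """

    n_perm: int = 10_000
    statistics: tuple[str, ...] = ("mean_diff",)
    alternative: str = "two_sided"
    seed: int = 0
    include_observed: bool = True
    exhaustive_max_n: int = 10

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for reported p-values")
        unknown = set(self.statistics) - set(STATISTICS)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")
        if self.alternative != "two_sided":
            raise ValueError("only two-sided alternatives are supported")


@dataclass(frozen=True)
class PermutationPlan:
    """A fixed set of group-label assignments over ``n1 + n2`` samples.

    ``order`` has one row per assignment; the first ``n1`` entries of a row
    are the indices assigned to group 1, the rest to group 2. Row 0 is the
    identity assignment when ``include_observed`` was requested (always for
    exhaustive plans).
    """

    n1: int
    n2: int
    order: np.ndarray = field(repr=False)
    exhaustive: bool = False

    @property
    def n_perm(self) -> int:
        return self.order.shape[0]

    def group1_indices(self) -> np.ndarray:
        return self.order[:, : self.n1]

    def group2_indices(self) -> np.ndarray:
        return self.order[:, self.n1 :]


def make_plan(n1: int, n2: int, cfg: PermConfig) -> PermutationPlan:
    """Build a permutation plan, exhaustive when the sample is small.

    For ``n1 + n2 <= cfg.exhaustive_max_n`` all ``C(n1+n2, n1)`` distinct
    group assignments are enumerated; otherwise ``cfg.n_perm`` assignments
    are sampled (with the identity first if ``cfg.include_observed``).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    n = n1 + n2
    if n <= cfg.exhaustive_max_n:
        rows = np.empty((comb(n, n1), n), dtype=np.intp)
        all_idx = frozenset(range(n))
        for i, chosen in enumerate(combinations(range(n), n1)):
            rows[i, :n1] = chosen
            rows[i, n1:] = sorted(all_idx - set(chosen))
        # put the identity assignment first
        ident = np.flatnonzero((rows[:, :n1] == np.arange(n1)).all(axis=1))[0]
        if ident != 0:
            rows[[0, ident]] = rows[[ident, 0]]
        return PermutationPlan(n1=n1, n2=n2, order=rows, exhaustive=True)

    rng = np.random.default_rng(cfg.seed)
    n_random = cfg.n_perm - int(cfg.include_observed)
    rows = np.empty((cfg.n_perm, n), dtype=np.intp)
    start = 0
    if cfg.include_observed:
        rows[0] = np.arange(n)
        start = 1
    sampled = rng.permuted(np.broadcast_to(np.arange(n), (n_random, n)), axis=1)
    # canonical within-group order: identical subsets then sum in identical
    # order, so exact ties at the observed statistic are counted as ties
    sampled[:, :n1].sort(axis=1)
    sampled[:, n1:].sort(axis=1)
    rows[start:] = sampled
    return PermutationPlan(n1=n1, n2=n2, order=rows, exhaustive=False)


def _group_moments(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-assignment mean and variance (ddof=1) of ``X`` rows selected by idx.

    X is (n, K); idx is (b, m); returns two (b, K) arrays.
    """
    sel = X[idx]  # (b, m, K)
    mean = sel.mean(axis=1)
    var = sel.var(axis=1, ddof=1)
    return mean, var


def perm_statistics(
    X: np.ndarray, plan: PermutationPlan, statistic: str
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one statistic on every assignment of the plan, per column.

    Parameters
    ----------
    X : (n, K) array
        Pooled sample values, group 1 rows first (rows ``0..n1-1``), one
        column per component.
    plan : PermutationPlan
    statistic : str
        One of :data:`STATISTICS`.

    Returns
    -------
    extremeness : (B, K) array
        Two-sided extremeness of the statistic on every assignment
        (``|T|`` for location statistics, ``max(r, 1/r)`` for the
        variance ratio).
    observed : (K,) array
        Signed statistic on the identity assignment (mean/median
        difference, or log variance ratio), used for sign reporting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (n, K)")
    n, K = X.shape
    if n != plan.n1 + plan.n2:
        raise ValueError("X row count does not match the plan")
    B = plan.n_perm
    U = np.empty((B, K))
    g1, g2 = plan.group1_indices(), plan.group2_indices()

    for lo in range(0, B, _CHUNK):
        hi = min(lo + _CHUNK, B)
        i1, i2 = g1[lo:hi], g2[lo:hi]
        if statistic == "mean_diff":
            T = X[i1].mean(axis=1) - X[i2].mean(axis=1)
            U[lo:hi] = np.abs(T)
        elif statistic == "median_diff":
            T = np.median(X[i1], axis=1) - np.median(X[i2], axis=1)
            U[lo:hi] = np.abs(T)
        elif statistic == "var_ratio":
            _, v1 = _group_moments(X, i1)
            _, v2 = _group_moments(X, i2)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = v1 / v2
                U[lo:hi] = np.maximum(r, 1.0 / r)
        else:  # pragma: no cover - guarded by PermConfig
            raise ValueError(f"unknown statistic {statistic!r}")

    x1, x2 = X[: plan.n1], X[plan.n1 :]
    if statistic == "mean_diff":
        observed = x1.mean(axis=0) - x2.mean(axis=0)
    elif statistic == "median_diff":
        observed = np.median(x1, axis=0) - np.median(x2, axis=0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            observed = np.log(x1.var(axis=0, ddof=1) / x2.var(axis=0, ddof=1))
    return U, np.atleast_1d(observed)


def pvalue_from_extremeness(U: np.ndarray, u_obs: np.ndarray) -> np.ndarray:
    """p = (# assignments with extremeness >= observed) / B, NaN-safe.

    Columns where the observed extremeness is NaN (degenerate data, e.g. a
    variance ratio with both groups constant) yield NaN.
    """
    B = U.shape[0]
    with np.errstate(invalid="ignore"):
        counts = (U >= u_obs[None, :]).sum(axis=0)
    p = counts / B
    p = np.where(np.isnan(u_obs), np.nan, p)
    return p


@dataclass
class PermTestResult:
    """p-value, signed observed statistic and degeneracy flag per statistic."""

    pvalues: dict[str, float]
    observed: dict[str, float]
    degenerate: dict[str, bool]
    n_perm: int
    exhaustive: bool


def univariate_perm_test(
    x1: np.ndarray, x2: np.ndarray, cfg: PermConfig, plan: PermutationPlan | None = None
) -> PermTestResult:
    """Two-sample permutation test of a single (scalar) component.

    A variance-ratio request on data where both groups are constant is
    flagged as degenerate (p-value NaN) rather than raising.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if plan is None:
        plan = make_plan(len(x1), len(x2), cfg)
    X = np.concatenate([x1, x2])[:, None]
    pvalues: dict[str, float] = {}
    observed: dict[str, float] = {}
    degenerate: dict[str, bool] = {}
    for stat in cfg.statistics:
        U, obs = perm_statistics(X, plan, stat)
        u_obs = U[0] if plan.order[0, : plan.n1].tolist() == list(range(plan.n1)) else None
        if u_obs is None:  # plan without identity row: recompute from data
            u_obs, _ = perm_statistics(X, _identity_plan(plan.n1, plan.n2), stat)
            u_obs = u_obs[0]
        p = pvalue_from_extremeness(U, u_obs)[0]
        pvalues[stat] = float(p)
        observed[stat] = float(obs[0])
        degenerate[stat] = bool(np.isnan(p))
    return PermTestResult(
        pvalues=pvalues,
        observed=observed,
        degenerate=degenerate,
        n_perm=plan.n_perm,
        exhaustive=plan.exhaustive,
    )


def _identity_plan(n1: int, n2: int) -> PermutationPlan:
    return PermutationPlan(
        n1=n1, n2=n2, order=np.arange(n1 + n2, dtype=np.intp)[None, :]
    )
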