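"""Shared exact-test statistics.

Fisher's exact test (two-sided, point-probability rule) is the workhorse of
the DMR caller: every candidate region is tested on the 2x2 table of pooled
methylated / unmethylated read counts of the two groups.  Two code paths are
provided:

* an exact integer path for small tables (total reads <= ``EXACT_TOTAL``):
  hypergeometric point masses are computed as exact integer numerators over a
  common denominator, so the "sum every table whose probability is <= the
  observed one" rule involves no floating-point tie ambiguity;
* a vectorised log-gamma path for arbitrarily large pooled tables, used by
  the region caller.  Ties on the opposite tail are detected with a 1e-7
  relative tolerance on the point mass (the convention of the mainstream
  implementations of this test).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = [
    "UndefinedTestError",
    "fisher_exact_two_sided",
    "fisher_exact_two_sided_vec",
    "bh_fdr",
]

EXACT_TOTAL = 1024
_TIE_REL_TOL = 1e-7


class UndefinedTestError(ValueError):
    """Raised for an all-zero 2x2 table, where the test is undefined."""


@lru_cache(maxsize=300_000)
def _hypergeom_numerators(N: int, K: int, n: int) -> tuple[int, tuple[int, ...]]:
    """Exact hypergeometric numerators C(K,x)*C(N-K,n-x) over the support.

    Returns (support_low, numerators); the common denominator is C(N, n).
    """
    lo = max(0, n - (N - K))
    hi = min(n, K)
    nums = tuple(math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1))
    return lo, nums


def fisher_exact_two_sided(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher's exact p for the table [[m_a, u_a], [m_b, u_b]].

    The p-value sums the probabilities of every table with the same margins
    whose point probability does not exceed the observed one.  Tables whose
    total is at most ``EXACT_TOTAL`` are evaluated with exact integer
    arithmetic; larger tables fall through to the vectorised float path.

    Raises
    ------
    UndefinedTestError
        If all four cells are zero.
    ValueError
        If any cell is negative.
    """
    cells = (m_a, u_a, m_b, u_b)
    if any(c < 0 for c in cells):
        raise ValueError(f"negative cell in 2x2 table: {cells}")
    N = sum(cells)
    if N == 0:
        raise UndefinedTestError("all-zero 2x2 table")
    if N > EXACT_TOTAL:
        out = fisher_exact_two_sided_vec(
            np.array([m_a]), np.array([u_a]), np.array([m_b]), np.array([u_b])
        )
        return float(out[0])
    K = m_a + m_b  # methylated-call margin
    n = m_a + u_a  # group-A margin
    lo, nums = _hypergeom_numerators(N, K, n)
    obs = nums[m_a - lo]
    total = sum(nums)
    tail = sum(v for v in nums if v <= obs)
    return tail / total


def _logpmf(x, N, K, n):
    """log P(X = x) for X ~ Hypergeom(N, K, n); inputs are float arrays."""
    return (
        gammaln(K + 1)
        - gammaln(x + 1)
        - gammaln(K - x + 1)
        + gammaln(N - K + 1)
        - gammaln(n - x + 1)
        - gammaln(N - K - n + x + 1)
        - gammaln(N + 1)
        + gammaln(n + 1)
        + gammaln(N - n + 1)
    )


def _tail_sum(start, step, bound, N, K, n, max_iter=40_000):
    """Sum hypergeometric pmf from ``start`` outward in direction ``step``.

    ``bound`` is the last index included in the support on that side.  The
    walk moves away from the mode, so terms decay; it stops early once the
    running term is negligible relative to the accumulated sum.
    """
    N = N.astype(float)
    K = K.astype(float)
    n = n.astype(float)
    i = start.astype(float)
    active = (i <= bound) if step > 0 else (i >= bound)
    safe_i = np.where(active, i, np.clip(i, np.maximum(0, n + K - N), np.minimum(n, K)))
    term = np.where(active, np.exp(_logpmf(safe_i, N, K, n)), 0.0)
    total = term.copy()
    for _ in range(max_iter):
        nxt = i + step
        in_range = np.where(step > 0, nxt <= bound, nxt >= bound)
        active = active & in_range & (term > total * 1e-18)
        if not active.any():
            break
        # pmf(i+1)/pmf(i) and pmf(i-1)/pmf(i) recurrences
        with np.errstate(divide="ignore", invalid="ignore"):
            up_ratio = ((K - i) * (n - i)) / ((i + 1) * (N - K - n + i + 1))
            dn_ratio = (i * (N - K - n + i)) / ((K - i + 1) * (n - i + 1))
        ratio = up_ratio if step > 0 else dn_ratio
        ratio = np.where(np.isfinite(ratio) & (ratio >= 0), ratio, 0.0)
        term = np.where(active, term * ratio, 0.0)
        total = total + term
        i = np.where(active, nxt, i)
    return total


def fisher_exact_two_sided_vec(m_a, u_a, m_b, u_b):
    """Vectorised two-sided Fisher's exact test on parallel 2x2 tables.

    Accepts equal-length integer arrays for the four cells and returns an
    array of p-values.  All-zero tables yield NaN (callers skip and log
    them).  Designed for the large pooled-count tables of region testing.
    """
    m_a = np.asarray(m_a, dtype=np.int64)
    u_a = np.asarray(u_a, dtype=np.int64)
    m_b = np.asarray(m_b, dtype=np.int64)
    u_b = np.asarray(u_b, dtype=np.int64)
    if np.any(m_a < 0) or np.any(u_a < 0) or np.any(m_b < 0) or np.any(u_b < 0):
        raise ValueError("negative cell in 2x2 table")
    N = m_a + u_a + m_b + u_b
    K = m_a + m_b
    n = m_a + u_a
    k = m_a

    ok = N > 0
    # work on safe copies to avoid invalid ops on empty tables
    Ns = np.where(ok, N, 2)
    Ks = np.where(ok, K, 1)
    ns = np.where(ok, n, 1)
    ks = np.where(ok, k, np.maximum(0, ns - (Ns - Ks)))

    lo = np.maximum(0, ns - (Ns - Ks))
    hi = np.minimum(ns, Ks)
    mode = ((ns + 1) * (Ks + 1)) // (Ns + 2)
    mode = np.clip(mode, lo, hi)

    fN, fK, fn = Ns.astype(float), Ks.astype(float), ns.astype(float)
    l_obs = _logpmf(ks.astype(float), fN, fK, fn)
    l_thr = l_obs + math.log1p(_TIE_REL_TOL)

    left = ks < mode
    right = ks > mode
    p = np.ones(Ns.shape, dtype=float)  # k at the mode -> every table counts

    if left.any():
        # opposite-tail boundary: smallest j in [mode, hi] with
        # logpmf(j) <= threshold (logpmf is non-increasing there)
        lo_b = mode.copy()
        hi_b = hi + 1
        while True:
            unresolved = (lo_b < hi_b) & left
            if not unresolved.any():
                break
            mid = (lo_b + hi_b) // 2
            cond = _logpmf(np.clip(mid, lo, hi).astype(float), fN, fK, fn) <= l_thr
            cond = cond | (mid > hi)
            hi_b = np.where(unresolved & cond, mid, hi_b)
            lo_b = np.where(unresolved & ~cond, mid + 1, lo_b)
        j = lo_b
        p_left = _tail_sum(ks, -1, lo, Ns, Ks, ns)
        has_right = j <= hi
        p_right = np.where(
            has_right,
            _tail_sum(np.where(has_right, j, hi), +1, hi, Ns, Ks, ns),
            0.0,
        )
        p = np.where(left, p_left + p_right, p)

    if right.any():
        # mirror: largest j in [lo, mode] with logpmf(j) <= threshold
        lo_b = lo - 1
        hi_b = mode.copy()
        while True:
            unresolved = (lo_b < hi_b) & right
            if not unresolved.any():
                break
            mid = (lo_b + hi_b + 1) // 2
            cond = _logpmf(np.clip(mid, lo, hi).astype(float), fN, fK, fn) <= l_thr
            cond = cond | (mid < lo)
            lo_b = np.where(unresolved & cond, mid, lo_b)
            hi_b = np.where(unresolved & ~cond, mid - 1, hi_b)
        j = lo_b
        p_right = _tail_sum(ks, +1, hi, Ns, Ks, ns)
        has_left = j >= lo
        p_left = np.where(
            has_left,
            _tail_sum(np.where(has_left, j, lo), -1, lo, Ns, Ks, ns),
            0.0,
        )
        p = np.where(right, p_left + p_right, p)

    p = np.minimum(p, 1.0)
    return np.where(ok, p, np.nan)


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j>=i} ( p_(j) * m / j ), capped at 1.  NaN entries are
    ignored for the correction (m excludes them) and reinserted as NaN in
    their original positions.

    Raises ``ValueError`` for p outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    finite = ~np.isnan(flat)
    vals = flat[finite]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        ranked = np.minimum(ranked, 1.0)
        out = np.empty(m)
        out[order] = ranked
        q[finite] = out
    return q.reshape(p.shape)
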