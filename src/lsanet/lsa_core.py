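"""Delay-limited local similarity scoring by dynamic programming.

Given two length-``n`` normalized profiles and a delay limit ``D``, the local
similarity (LS) score is the largest length-normalized running sum of products
``zx_i * zy_j`` over contiguous cell runs with a constant offset ``|i - j| <= D``
— a Smith-Waterman-style maximum-subarray statistic on each allowed diagonal.
Positive runs (``P`` table) capture co-varying stretches, negative runs
(``N`` table, products negated) capture contrary-varying stretches; the score's
sign records which dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LsaParams:
    """Scoring parameters.

    ``delay_limit`` is the maximum allowed offset ``|i - j|`` between aligned
    time points.  Statistical power drops as the limit grows; keeping the
    number of time points above ``5 + delay_limit`` is recommended.
    """

    delay_limit: int = 3

    def validate(self, n: int) -> None:
        if self.delay_limit < 0:
            raise ValueError("delay_limit must be non-negative")
        if self.delay_limit > n - 1:
            raise ValueError(f"delay_limit {self.delay_limit} exceeds n - 1 = {n - 1}")


@dataclass
class LsaResult:
    """LS score with its aligned interval.

    ``score = sign * magnitude`` with ``magnitude = max(p_max, n_max) / n``.
    ``xs``/``ys`` are 1-based starts of the aligned interval in X and Y,
    ``length`` its number of time points, and ``delay = xs - ys``.
    """

    score: float
    magnitude: float
    sign: int
    p_max: float
    n_max: float
    xs: int
    ys: int
    length: int

    @property
    def delay(self) -> int:
        return self.xs - self.ys


def _check_profiles(zx: np.ndarray, zy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    zx = np.asarray(zx, dtype=float)
    zy = np.asarray(zy, dtype=float)
    if zx.ndim != 1 or zy.ndim != 1:
        raise ValueError("profiles must be one-dimensional")
    if zx.size != zy.size:
        raise ValueError(f"profile lengths differ: {zx.size} vs {zy.size}")
    if zx.size == 0:
        raise ValueError("profiles are empty")
    if not (np.isfinite(zx).all() and np.isfinite(zy).all()):
        raise ValueError("profiles contain non-finite values (fill missing data first)")
    return zx, zy


def local_similarity(zx: np.ndarray, zy: np.ndarray, params: LsaParams) -> LsaResult:
    """Score two normalized profiles and recover the best aligned interval.

    The recurrences, over cells with ``|i - j| <= delay_limit`` and zero
    boundaries, are::

        P[i, j] = max(0, P[i-1, j-1] + zx[i] * zy[j])
        N[i, j] = max(0, N[i-1, j-1] - zx[i] * zy[j])

    The winning cell (ties broken toward the smallest ``(i, j)`` in row-major
    order; a ``p_max == n_max`` tie reports a positive sign) is traced back
    along its diagonal to the most recent reset to zero.
    """
    zx, zy = _check_profiles(zx, zy)
    n = zx.size
    params.validate(n)
    D = params.delay_limit

    P = np.zeros((n + 1, n + 1))
    N = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        lo = max(1, i - D)
        hi = min(n, i + D)
        for j in range(lo, hi + 1):
            s = zx[i - 1] * zy[j - 1]
            P[i, j] = max(0.0, P[i - 1, j - 1] + s)
            N[i, j] = max(0.0, N[i - 1, j - 1] - s)

    p_max = float(P.max())
    n_max = float(N.max())
    sign = 1 if p_max >= n_max else -1
    magnitude = max(p_max, n_max) / n
    if magnitude == 0.0:
        return LsaResult(0.0, 0.0, 1, p_max, n_max, xs=1, ys=1, length=0)

    table = P if sign > 0 else N
    # argmax on the flattened table returns the first maximum in row-major
    # order, i.e. the smallest (i, j)
    i, j = divmod(int(table.argmax()), n + 1)
    k = 0
    while table[i - 1 - k, j - 1 - k] > 0.0:
        k += 1
    return LsaResult(
        score=sign * magnitude,
        magnitude=magnitude,
        sign=sign,
        p_max=p_max,
        n_max=n_max,
        xs=i - k,
        ys=j - k,
        length=k + 1,
    )


def batch_max_scores(
    zx_rows: np.ndarray, zy: np.ndarray, delay_limit: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized ``(p_max, n_max)`` for many X profiles against one Y.

    Used on the hot paths (permutation and bootstrap resampling) where only
    the score is needed.  Per diagonal, the clipped running-sum recurrence is
    evaluated in closed form: with prefix sums ``s`` of the products, the best
    positive run ending at ``k`` is ``s_k - min_{j<=k} s_j`` and the best
    negative run is ``max_{j<=k} s_j - s_k``.
    """
    ZX = np.atleast_2d(np.asarray(zx_rows, dtype=float))
    zy = np.asarray(zy, dtype=float)
    L, n = ZX.shape
    if zy.size != n:
        raise ValueError("profile lengths differ")
    if delay_limit < 0 or delay_limit > n - 1:
        raise ValueError("invalid delay limit")
    p_max = np.zeros(L)
    n_max = np.zeros(L)
    zeros = np.zeros((L, 1))
    for d in range(-delay_limit, delay_limit + 1):
        if d >= 0:
            xi = np.arange(d, n)
        else:
            xi = np.arange(0, n + d)
        yj = xi - d
        w = ZX[:, xi] * zy[yj]
        s = np.hstack([zeros, np.cumsum(w, axis=1)])
        np.maximum(p_max, (s - np.minimum.accumulate(s, axis=1)).max(axis=1), out=p_max)
        np.maximum(n_max, (np.maximum.accumulate(s, axis=1) - s).max(axis=1), out=n_max)
    return p_max, n_max


def signed_score(zx: np.ndarray, zy: np.ndarray, delay_limit: int) -> float:
    """Signed, length-normalized LS score (no interval recovery)."""
    zx, zy = _check_profiles(zx, zy)
    p, nn = batch_max_scores(zx[None, :], zy, delay_limit)
    n = zx.size
    return float(p[0] / n if p[0] >= nn[0] else -nn[0] / n)


def brute_force_ls(zx: np.ndarray, zy: np.ndarray, params: LsaParams) -> LsaResult:
    """Exhaustive-enumeration oracle for :func:`local_similarity`.

    Enumerates every offset ``d`` in ``[-D, D]`` and every contiguous window on
    that diagonal, tracking the best positive and best negated window sum.
    O(n^3) — intended for small test instances only, and kept deliberately
    independent of the dynamic program it checks.
    """
    zx, zy = _check_profiles(zx, zy)
    n = zx.size
    params.validate(n)
    D = params.delay_limit

    best_pos = 0.0
    best_neg = 0.0
    pos_iv = (1, 1, 0)  # (xs, ys, length)
    neg_iv = (1, 1, 0)
    for d in range(-D, D + 1):
        # cells (i, j) with i - j = d, 1-based
        i_start = max(1, 1 + d)
        i_end = min(n, n + d)
        for a in range(i_start, i_end + 1):
            total = 0.0
            for b in range(a, i_end + 1):
                total += zx[b - 1] * zy[b - d - 1]
                if total > best_pos:
                    best_pos = total
                    pos_iv = (a, a - d, b - a + 1)
                if -total > best_neg:
                    best_neg = -total
                    neg_iv = (a, a - d, b - a + 1)
    sign = 1 if best_pos >= best_neg else -1
    magnitude = max(best_pos, best_neg) / n
    xs, ys, length = pos_iv if sign > 0 else neg_iv
    if magnitude == 0.0:
        return LsaResult(0.0, 0.0, 1, best_pos, best_neg, xs=1, ys=1, length=0)
    return LsaResult(
        score=sign * magnitude,
        magnitude=magnitude,
        sign=sign,
        p_max=best_pos,
        n_max=best_neg,
        xs=xs,
        ys=ys,
        length=length,
    )
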