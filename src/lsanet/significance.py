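"""Statistical evidence for pairwise associations.

Four independent pieces: Pearson correlation with its t-test, a permutation
p-value for the LS score, a bootstrap percentile confidence interval exploiting
replicates, and Storey q-values for multiple-testing control across all pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ReplicatedSeries
from .lsa_core import LsaParams, batch_max_scores, signed_score
from .summarize import normal_score, summarize


@dataclass
class PccResult:
    """Pearson correlation ``r`` and its two-sided t-test p-value."""

    r: float
    p: float


@dataclass
class InferenceParams:
    """Resampling-inference settings.

    ``num_permutations`` (L) and ``num_bootstraps`` (B) of 0 disable the
    respective procedure; ``alpha`` is the type-I level of the CI.
    """

    num_permutations: int = 1000
    num_bootstraps: int = 100
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.num_permutations < 0 or self.num_bootstraps < 0:
            raise ValueError("permutation/bootstrap counts must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def pearson(profile_x: np.ndarray, profile_y: np.ndarray) -> PccResult:
    """Pearson correlation of two mean profiles with a two-sided t-test.

    The statistic ``t = r * sqrt((n - 2) / (1 - r^2))`` is referred to a
    t-distribution with ``n - 2`` degrees of freedom.  A zero-variance profile
    leaves ``r`` undefined; (0, 1) is returned with a warning.
    """
    x = np.asarray(profile_x, dtype=float)
    y = np.asarray(profile_y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("profiles must be one-dimensional and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson test needs at least 3 time points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance profile: correlation undefined, reporting r=0, p=1",
                      RuntimeWarning, stacklevel=2)
        return PccResult(0.0, 1.0)
    r = float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return PccResult(r, 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return PccResult(r, min(p, 1.0))


def permutation_pvalue(
    zx: np.ndarray,
    zy: np.ndarray,
    observed_magnitude: float,
    params: LsaParams,
    inf: InferenceParams,
    rng: np.random.Generator | None = None,
    conservative: bool = False,
) -> float | None:
    """Permutation p-value for an observed LS magnitude.

    ``Y`` is held fixed while the time order of the normalized ``X`` profile is
    reshuffled ``L`` times; the p-value is the fraction of reshuffles whose LS
    magnitude reaches the observed one.  The magnitude already maximizes over
    both association signs, so the test is two-sided by construction.  The
    plain proportion is reported by default (0 is attainable);
    ``conservative=True`` switches to ``(count + 1) / (L + 1)``.
    """
    L = inf.num_permutations
    if L == 0:
        return None
    zx = np.asarray(zx, dtype=float)
    zy = np.asarray(zy, dtype=float)
    if rng is None:
        rng = np.random.default_rng(inf.rng_seed)
    perms = rng.permuted(np.broadcast_to(zx, (L, zx.size)), axis=1)
    p_max, n_max = batch_max_scores(perms, zy, params.delay_limit)
    magnitudes = np.maximum(p_max, n_max) / zx.size
    exceed = int(np.count_nonzero(magnitudes >= observed_magnitude))
    if conservative:
        return (exceed + 1) / (L + 1)
    return exceed / L


def bootstrap_ci(
    x: ReplicatedSeries,
    y: ReplicatedSeries,
    method: str,
    params: LsaParams,
    inf: InferenceParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, float] | None:
    """Percentile bootstrap CI for the signed LS score.

    Each round independently resamples the ``m`` replicates with replacement at
    every time point of X and of Y, then re-summarizes, re-normalizes and
    re-scores.  The interval spans the ``ceil(B * alpha / 2)``-th and
    ``ceil(B * (1 - alpha / 2))``-th order statistics of the B scores.  With a
    single replicate every resample reproduces the input, so the interval
    degenerates to the observed score.
    """
    B = inf.num_bootstraps
    if B == 0:
        return None
    if x.has_missing or y.has_missing:
        raise ValueError("bootstrap requires filled series")
    if x.n != y.n or x.m != y.m:
        raise ValueError("series shapes differ")
    n, m = x.n, x.m
    if rng is None:
        rng = np.random.default_rng(inf.rng_seed)
    rows = np.arange(n)[:, None]
    scores = np.empty(B)
    for b in range(B):
        rx = x.values[rows, rng.integers(0, m, size=(n, m))]
        ry = y.values[rows, rng.integers(0, m, size=(n, m))]
        zx = normal_score(summarize(rx, method))
        zy = normal_score(summarize(ry, method))
        scores[b] = signed_score(zx, zy, params.delay_limit)
    scores.sort()
    lo = max(math.ceil(B * inf.alpha / 2), 1)
    hi = min(math.ceil(B * (1 - inf.alpha / 2)), B)
    return float(scores[lo - 1]), float(scores[hi - 1])


def _estimate_pi0(pvalues: np.ndarray) -> float:
    """Estimate the null proportion pi0 on the lambda grid 0, 0.05, ..., 0.90.

    ``pi0(lambda) = #{p > lambda} / (N * (1 - lambda))`` is smoothed by a cubic
    polynomial and evaluated at the largest lambda, then clamped into (0, 1].
    """
    lambdas = np.arange(0.0, 0.91, 0.05)
    pi0_grid = np.array([(pvalues > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_grid, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return min(1.0, max(pi0, 1e-8))


def storey_qvalues(pvalues) -> np.ndarray:
    """Storey q-values: the FDR incurred when each test is called significant.

    For sorted p-values, ``q_(i) = min_{j >= i} pi0 * N * p_(j) / j`` with
    ``pi0`` from :func:`_estimate_pi0`; the output follows the input order and
    is capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a one-dimensional, non-empty p-value array")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    N = p.size
    pi0 = _estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * N * p[order] / np.arange(1, N + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(N)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
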