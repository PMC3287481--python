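"""Replicate summarization (F-transform) and rank-based normal-score scaling.

Each time point's ``m`` replicates are collapsed to a scalar by one of four
summarizing functions, and the resulting length-``n`` profile is mapped through
the inverse standard-normal CDF of its ranks so that local-similarity scoring
operates on (approximately) standard-normal margins regardless of the raw
measurement scale.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm, rankdata

#: recognised summarizing functions
SUMMARY_METHODS = ("simple", "sd", "med", "mad")

# floor for a per-time-point dispersion estimate; identical replicates would
# otherwise divide by zero in the 'sd'/'mad' ratios
_DISPERSION_FLOOR = 1e-12


def _guarded_ratio(center: np.ndarray, spread: np.ndarray, what: str) -> np.ndarray:
    degenerate = spread < _DISPERSION_FLOOR
    if degenerate.any():
        warnings.warn(
            f"zero {what} at time point(s) {np.flatnonzero(degenerate) + 1}; "
            f"clamping the denominator at {_DISPERSION_FLOOR:g}",
            RuntimeWarning,
            stacklevel=3,
        )
    return center / np.maximum(spread, _DISPERSION_FLOOR)


def summarize(replicates: np.ndarray, method: str) -> np.ndarray:
    """Collapse an ``n x m`` replicate grid to a length-``n`` profile.

    * ``simple`` — per-time-point mean.
    * ``sd``     — mean divided by the replicate standard deviation (ddof=1),
      down-weighting noisy time points.
    * ``med``    — per-time-point median (robust to outliers).
    * ``mad``    — median divided by the median absolute deviation.

    ``sd`` and ``mad`` need at least two replicates; with one replicate the
    dispersion is undefined.
    """
    x = np.asarray(replicates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("replicates must be an n x m grid")
    if not np.isfinite(x).all():
        raise ValueError("replicate grid contains non-finite values (fill missing data first)")
    if method not in SUMMARY_METHODS:
        raise ValueError(f"unknown summarizing method {method!r}; choose from {SUMMARY_METHODS}")
    m = x.shape[1]
    if method in ("sd", "mad") and m < 2:
        raise ValueError(f"method {method!r} needs at least 2 replicates (m={m})")

    if method == "simple":
        return x.mean(axis=1)
    if method == "med":
        return np.median(x, axis=1)
    if method == "sd":
        return _guarded_ratio(x.mean(axis=1), x.std(axis=1, ddof=1), "replicate SD")
    med = np.median(x, axis=1)
    mad = np.median(np.abs(x - med[:, None]), axis=1)
    return _guarded_ratio(med, mad, "replicate MAD")


def normal_score(profile: np.ndarray) -> np.ndarray:
    """Map a profile to normal scores: ``z_i = Phi^-1(r_i / (n + 1))``.

    ``r_i`` is the (midrank-resolved) rank of value ``i`` among the ``n``
    values; the ``n + 1`` divisor keeps every argument strictly inside (0, 1).
    The result depends only on the ranks, so any strictly increasing transform
    of the input leaves it unchanged.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    n = x.size
    if n < 2:
        raise ValueError("need at least two time points to normalize")
    if not np.isfinite(x).all():
        raise ValueError("profile contains non-finite values")
    return norm.ppf(rankdata(x) / (n + 1))
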