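"""All-pairs analysis: fill, transform, score, test, and FDR-correct.

Per pair: the replicate grids are summarized and normal-score normalized, the
delay-limited LS score and its aligned interval are computed, a permutation
test attaches a p-value, the bootstrap (when replicates exist) attaches a CI,
and Pearson correlation on the replicate-mean profiles is reported alongside.
Storey q-values are then computed across all pairs, separately for the LS and
the Pearson p-values.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .data_io import FILL_METHODS, Dataset, ReplicatedSeries
from .lsa_core import LsaParams, local_similarity
from .significance import (
    InferenceParams,
    bootstrap_ci,
    pearson,
    permutation_pvalue,
    storey_qvalues,
)
from .summarize import SUMMARY_METHODS, normal_score, summarize


@dataclass
class AnalysisConfig:
    """User-facing parameters of one analysis run."""

    delay_limit: int = 3
    transform: str = "simple"
    fill: str = "none"
    num_permutations: int = 1000
    num_bootstraps: int = 100
    alpha: float = 0.05
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.transform not in SUMMARY_METHODS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.fill not in FILL_METHODS:
            raise ValueError(f"unknown fill method {self.fill!r}")
        for name in ("p_threshold", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def lsa_params(self) -> LsaParams:
        return LsaParams(delay_limit=self.delay_limit)

    @property
    def inference_params(self) -> InferenceParams:
        return InferenceParams(
            num_permutations=self.num_permutations,
            num_bootstraps=self.num_bootstraps,
            alpha=self.alpha,
            rng_seed=self.rng_seed,
        )


@dataclass
class PairRecord:
    """One row of the pairwise result table."""

    x_id: str
    y_id: str
    ls: float
    xs: int
    ys: int
    length: int
    p: float | None
    pcc: float
    p_pcc: float
    low_ci: float | None = None
    up_ci: float | None = None
    q: float | None = None
    q_pcc: float | None = None

    @property
    def delay(self) -> int:
        return self.xs - self.ys


def _pair_rng(seed: int, x_id: str, y_id: str, stream: int) -> np.random.Generator:
    # per-pair deterministic substream keyed by the factor labels, so results
    # depend neither on pair evaluation order nor on input row order
    key = (zlib.crc32(x_id.encode()), zlib.crc32(y_id.encode()), stream)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def analyze_pair(
    x: ReplicatedSeries,
    y: ReplicatedSeries,
    config: AnalysisConfig,
    x_id: str = "X",
    y_id: str = "Y",
) -> PairRecord:
    """Analyze one pair of filled series; q-value fields are left unset.

    The permutation and bootstrap substreams are seeded from
    ``config.rng_seed`` and the factor labels, so an all-pairs run is
    independent of pair evaluation order and of input row order.
    """
    if x.has_missing or y.has_missing:
        raise ValueError(
            "missing values reached the scoring stage; choose a fill method other than 'none'"
        )
    if x.n != y.n or x.m != y.m:
        raise ValueError("the two series must share n and m")

    zx = normal_score(summarize(x.values, config.transform))
    zy = normal_score(summarize(y.values, config.transform))
    result = local_similarity(zx, zy, config.lsa_params)

    inf = config.inference_params
    p = None
    if inf.num_permutations > 0:
        p = permutation_pvalue(
            zx, zy, result.magnitude, config.lsa_params, inf,
            rng=_pair_rng(config.rng_seed, x_id, y_id, 0),
        )
    ci = None
    if x.m > 1 and inf.num_bootstraps > 0:
        ci = bootstrap_ci(
            x, y, config.transform, config.lsa_params, inf,
            rng=_pair_rng(config.rng_seed, x_id, y_id, 1),
        )

    if x.n >= 3:
        pcc = pearson(x.replicate_mean(), y.replicate_mean())
        r, p_pcc = pcc.r, pcc.p
    else:
        warnings.warn("fewer than 3 time points: Pearson test undefined", RuntimeWarning)
        r, p_pcc = np.nan, np.nan

    return PairRecord(
        x_id=x_id, y_id=y_id,
        ls=result.score, xs=result.xs, ys=result.ys, length=result.length,
        p=p, pcc=r, p_pcc=p_pcc,
        low_ci=None if ci is None else ci[0],
        up_ci=None if ci is None else ci[1],
    )


def iter_pairs(T: int) -> Iterator[tuple[int, int]]:
    """Unordered factor-index pairs, X before Y in input order."""
    for i in range(T):
        for j in range(i + 1, T):
            yield i, j


def analyze_all(
    dataset: Dataset,
    config: AnalysisConfig,
    progress: Callable[[int], None] | None = None,
) -> list[PairRecord]:
    """Run the full pipeline over every unordered factor pair.

    Returns ``T * (T - 1) / 2`` records with Storey q-values attached across
    all LS p-values and, separately, across all Pearson p-values.  The list is
    unfiltered; apply :func:`filter_records` (or thresholds at network-build
    time) to select significant pairs.
    """
    if dataset.T < 2:
        raise ValueError("need at least two factors")
    ds = dataset.fill_missing(config.fill)
    records: list[PairRecord] = []
    for count, (i, j) in enumerate(iter_pairs(ds.T), start=1):
        records.append(
            analyze_pair(
                ds.series[i], ds.series[j], config,
                x_id=ds.factor_ids[i], y_id=ds.factor_ids[j],
            )
        )
        if progress is not None and count % 1000 == 0:
            progress(count)

    if all(r.p is not None for r in records):
        for r, q in zip(records, storey_qvalues([r.p for r in records])):
            r.q = float(q)
    pcc_ps = [r.p_pcc for r in records]
    if np.isfinite(pcc_ps).all():
        for r, q in zip(records, storey_qvalues(pcc_ps)):
            r.q_pcc = float(q)
    return records


def filter_records(
    records: list[PairRecord],
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> list[PairRecord]:
    """Keep records meeting both thresholds (missing p or q passes trivially)."""
    kept = []
    for r in records:
        if r.p is not None and r.p > p_threshold:
            continue
        if r.q is not None and r.q > q_threshold:
            continue
        kept.append(r)
    return kept
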