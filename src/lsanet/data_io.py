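"""Read and write replicated time-series matrices and result tables.

The on-disk matrix dialect is tab-delimited: one header row, then one row per
factor (OTU, gene, environmental variable).  Columns after the factor label
hold ``n`` time points with ``m`` replicates each in *time-major* order
(t1r1 ... t1rm, t2r1 ... t2rm, ...).  Cells equal to the missing token
(default ``na``, case-insensitive) or empty are treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d

#: recognised missing-value policies; all but "none" remove the mask entirely
FILL_METHODS = ("none", "zero", "linear", "quadratic", "cubic", "nearest")

# minimum observed points per replicate column for each interpolation kind
# (k+1 for a spline of order k; a single point suffices for hold/nearest)
_MIN_OBSERVED = {"zero": 1, "nearest": 1, "linear": 2, "quadratic": 3, "cubic": 4}

#: fixed column set of the pairwise result table
RESULT_COLUMNS = (
    "X", "Y", "LS", "lowCI", "upCI", "Xs", "Ys", "Len", "D",
    "P", "PCC", "Ppcc", "Q", "Qpcc",
)

DEFAULT_MISSING_TOKEN = "na"


@dataclass
class ReplicatedSeries:
    """One factor's raw measurements: an ``n x m`` grid plus a missing mask."""

    values: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be an n x m grid")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.ndim == 1:
                self.missing_mask = self.missing_mask[:, None]
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def replicate_mean(self) -> np.ndarray:
        """Per-time-point mean over replicates (requires a filled series)."""
        if self.has_missing:
            raise ValueError("series still contains missing values")
        return self.values.mean(axis=1)


def fill_missing(series: ReplicatedSeries, method: str, label: str = "") -> ReplicatedSeries:
    """Impute missing cells along the time axis, one replicate column at a time.

    Interior gaps are interpolated (zero-order hold, spline of order 1-3, or
    nearest neighbour); leading and trailing gaps take the value of the nearest
    observed point (constant extrapolation).  ``method="none"`` returns an
    untouched copy; downstream scoring rejects any surviving missing values.
    """
    if method not in FILL_METHODS:
        raise ValueError(f"unknown fill method {method!r}; choose from {FILL_METHODS}")
    if method == "none" or not series.has_missing:
        return ReplicatedSeries(series.values.copy(), series.missing_mask.copy())

    n, m = series.n, series.m
    t = np.arange(n, dtype=float)
    vals = series.values.copy()
    for r in range(m):
        observed = ~series.missing_mask[:, r]
        if observed.all():
            continue
        k = int(observed.sum())
        need = _MIN_OBSERVED[method]
        if k < need:
            where = f" of factor {label!r}" if label else ""
            raise ValueError(
                f"replicate {r + 1}{where} has {k} observed point(s); "
                f"{method!r} interpolation needs at least {need}"
            )
        obs_t = t[observed]
        obs_v = series.values[observed, r]
        gaps = ~observed
        if k == 1:
            vals[gaps, r] = obs_v[0]
            continue
        f = interp1d(
            obs_t, obs_v, kind=method, bounds_error=False,
            fill_value=(obs_v[0], obs_v[-1]),
        )
        vals[gaps, r] = f(t[gaps])
    return ReplicatedSeries(vals, np.zeros((n, m), dtype=bool))


@dataclass
class Dataset:
    """A matrix of factors, each a :class:`ReplicatedSeries` on a shared grid."""

    factor_ids: list[str]
    series: list[ReplicatedSeries]
    n: int
    m: int

    def __post_init__(self) -> None:
        if len(self.factor_ids) != len(self.series):
            raise ValueError("factor_ids and series lengths differ")
        if len(set(self.factor_ids)) != len(self.factor_ids):
            raise ValueError("factor labels must be unique")
        if self.n < 2:
            raise ValueError("need at least two time points")
        if self.m < 1:
            raise ValueError("need at least one replicate")
        for fid, s in zip(self.factor_ids, self.series):
            if s.n != self.n or s.m != self.m:
                raise ValueError(f"factor {fid!r} grid is {s.n}x{s.m}, expected {self.n}x{self.m}")

    @property
    def T(self) -> int:
        return len(self.factor_ids)

    def fill_missing(self, method: str) -> "Dataset":
        filled = [fill_missing(s, method, label=fid) for fid, s in zip(self.factor_ids, self.series)]
        return Dataset(list(self.factor_ids), filled, self.n, self.m)


def read_matrix(
    path,
    spot_count: int,
    replicate_count: int,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> Dataset:
    """Parse a tab-delimited replicated matrix into a :class:`Dataset`.

    ``spot_count`` and ``replicate_count`` fix the expected row width
    (``1 + spot_count * replicate_count`` fields); the first row is a header
    and is skipped.
    """
    if spot_count < 2 or replicate_count < 1:
        raise ValueError("spot_count must be >= 2 and replicate_count >= 1")
    expected = spot_count * replicate_count
    token = missing_token.strip().lower()

    factor_ids: list[str] = []
    series: list[ReplicatedSeries] = []
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        label = fields[0]
        if len(fields) - 1 != expected:
            raise ValueError(
                f"{path}:{lineno}: factor {label!r} has {len(fields) - 1} data fields, "
                f"expected {expected} ({spot_count} spots x {replicate_count} replicates)"
            )
        if label in factor_ids:
            raise ValueError(f"{path}:{lineno}: duplicate factor label {label!r}")
        values = np.zeros((spot_count, replicate_count))
        mask = np.zeros((spot_count, replicate_count), dtype=bool)
        for idx, cell in enumerate(fields[1:]):
            i, r = divmod(idx, replicate_count)
            stripped = cell.strip()
            if stripped == "" or stripped.lower() == token:
                mask[i, r] = True
                values[i, r] = np.nan
                continue
            try:
                values[i, r] = float(stripped)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: factor {label!r}, time point {i + 1}, "
                    f"replicate {r + 1}: non-numeric cell {cell!r}"
                ) from None
        factor_ids.append(label)
        series.append(ReplicatedSeries(values, mask))
    return Dataset(factor_ids, series, spot_count, replicate_count)


def write_matrix(dataset: Dataset, path, missing_token: str = DEFAULT_MISSING_TOKEN) -> None:
    """Write a :class:`Dataset` in the dialect that :func:`read_matrix` accepts.

    Numeric cells use ``repr`` so that a write/read cycle round-trips exactly.
    """
    header = ["#factor"]
    for i in range(1, dataset.n + 1):
        for r in range(1, dataset.m + 1):
            header.append(f"t{i}r{r}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for fid, s in zip(dataset.factor_ids, dataset.series):
            cells = [fid]
            for i in range(dataset.n):
                for r in range(dataset.m):
                    cells.append(missing_token if s.missing_mask[i, r] else repr(float(s.values[i, r])))
            fh.write("\t".join(cells) + "\n")


def _fmt(value, decimals: int | None = None) -> str:
    if value is None:
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    v = float(value)
    if np.isnan(v):
        return ""
    if decimals is not None:
        return f"{v:.{decimals}f}"
    return f"{v:.6g}"


def write_results(records: Sequence, path) -> None:
    """Write pairwise records as a tab-delimited table with the 14 fixed columns.

    ``lowCI``/``upCI`` are left empty when the bootstrap was disabled; the ``D``
    column is always ``Xs - Ys``.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for rec in records:
            row = [
                str(rec.x_id), str(rec.y_id), _fmt(rec.ls),
                _fmt(rec.low_ci), _fmt(rec.up_ci),
                str(int(rec.xs)), str(int(rec.ys)), str(int(rec.length)),
                str(int(rec.xs) - int(rec.ys)),
                _fmt(rec.p), _fmt(rec.pcc), _fmt(rec.p_pcc),
                _fmt(rec.q), _fmt(rec.q_pcc),
            ]
            fh.write("\t".join(row) + "\n")


def read_results(path) -> list:
    """Read a result table written by :func:`write_results` back into records."""
    from .pipeline import PairRecord  # local import to avoid a cycle

    def opt_float(cell: str):
        cell = cell.strip()
        return None if cell == "" else float(cell)

    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise ValueError(f"{path}: unexpected result header {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(RESULT_COLUMNS):
                raise ValueError(f"{path}: malformed result row {f[0]!r}")
            records.append(PairRecord(
                x_id=f[0], y_id=f[1], ls=float(f[2]),
                low_ci=opt_float(f[3]), up_ci=opt_float(f[4]),
                xs=int(f[5]), ys=int(f[6]), length=int(f[7]),
                p=opt_float(f[9]), pcc=opt_float(f[10]), p_pcc=opt_float(f[11]),
                q=opt_float(f[12]), q_pcc=opt_float(f[13]),
            ))
    return records
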