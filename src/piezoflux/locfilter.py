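"""Filtering and merging of raw 3D-MINFLUX localizations into trace centers.

MINFLUX exports one row per valid localization, keyed by a trace
identification number (TID) that groups the localizations of one continuous
DNA-PAINT binding event.  The post-processing cascade implemented here is:

1. per-localization quality filter on cfr (center frequency ratio) and efo
   (effective frequency at offset, kHz) to reject multi-emitter events;
2. grouping by TID;
3. per-trace filter: traces with fewer than ``min_locs`` localizations or a
   sample standard deviation above ``max_axis_sd`` on any axis are dropped;
4. trimming of the first ``trim_head`` localizations of each trace (early
   localizations tend to sit apart from the main cloud);
5. z rescaling by ``z_scale`` to correct the refractive-index mismatch
   between coverslip and sample;
6. per-trace center of mass (unweighted mean of the member coordinates).

All coordinates are in nanometres throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

#: Canonical CSV dialect: comma-separated, UTF-8, '.' decimal.
LOC_COLUMNS = ("tid", "x_nm", "y_nm", "z_nm", "cfr", "efo", "t_s")
CENTER_COLUMNS = ("tid", "x_nm", "y_nm", "z_nm", "n_locs")

_AXES = ("x_nm", "y_nm", "z_nm")


class FormatError(ValueError):
    """Raised when a localization table does not match the expected dialect."""


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the localization-filter cascade.

    Attributes
    ----------
    cfr_max:
        Keep localizations with cfr <= this value.
    efo_max:
        Absolute efo cutoff in kHz, or ``None`` to derive the cutoff from the
        data as the ``efo_percentile``-th percentile of the per-localization
        efo values (upper cut against multi-emitter contamination).
    min_locs:
        Minimum number of localizations a trace must have to survive.
    max_axis_sd:
        A trace is excluded if its sample SD exceeds this on ANY single axis
        (strict ``>``; ties at the bound are kept).
    trim_head:
        Number of leading localizations (time order) removed per trace.
    z_scale:
        Multiplicative z correction for the refractive-index mismatch.
    """

    cfr_max: float = 0.8
    efo_max: float | None = None
    efo_percentile: float = 95.0
    min_locs: int = 3
    max_axis_sd: float = 10.0
    trim_head: int = 2
    z_scale: float = 0.7

    def __post_init__(self) -> None:
        for name in ("cfr_max", "efo_percentile", "max_axis_sd", "z_scale"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.efo_max is not None and (not np.isfinite(self.efo_max) or self.efo_max <= 0):
            raise ValueError("efo_max must be positive and finite or None")
        if self.min_locs < 1:
            raise ValueError("min_locs must be >= 1")
        if self.trim_head < 0:
            raise ValueError("trim_head must be >= 0")


@dataclass(frozen=True)
class Trace:
    """One DNA-PAINT emission trace: the localizations sharing a TID."""

    trace_id: int
    locs: pd.DataFrame  # ordered by t_s

    @property
    def n_locs(self) -> int:
        return len(self.locs)

    @property
    def axis_sd(self) -> np.ndarray:
        """Per-axis sample (n-1) standard deviation in nm; NaN for n < 2."""
        return self.locs[list(_AXES)].std(ddof=1).to_numpy()


class TraceSet:
    """Localization table grouped by TID, ordered by time within a trace.

    Thin wrapper keeping the data in a single DataFrame so the filter stages
    stay vectorized; iteration yields :class:`Trace` views.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = (
            table.sort_values(["tid", "t_s"], kind="stable").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return int(self.table["tid"].nunique())

    def __iter__(self) -> Iterator[Trace]:
        for tid, grp in self.table.groupby("tid", sort=True):
            yield Trace(int(tid), grp.reset_index(drop=True))

    @property
    def trace_ids(self) -> np.ndarray:
        return np.sort(self.table["tid"].unique())


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization CSV in the canonical dialect.

    Raises
    ------
    FormatError
        If a required column is missing (the error names it) or a cell is
        non-numeric (the error carries the 1-based file line number).
    """
    df = pd.read_csv(path)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    out = df.loc[:, list(LOC_COLUMNS)].copy()
    for col in LOC_COLUMNS:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            line = int(bad.idxmax()) + 2
            raise FormatError(
                f"non-numeric or missing value in column {col!r} at line {line}"
            )
        out[col] = coerced
    if not np.isfinite(out[list(_AXES)].to_numpy()).all():
        raise FormatError("non-finite coordinate value")
    out["tid"] = out["tid"].astype(np.int64)
    return out


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, list(LOC_COLUMNS)].to_csv(path, index=False)


def resolve_efo_cutoff(table: pd.DataFrame, config: FilterConfig) -> float:
    """Absolute efo cutoff in kHz: configured value or per-dataset percentile."""
    if config.efo_max is not None:
        return float(config.efo_max)
    if len(table) == 0:
        return float("inf")
    return float(np.percentile(table["efo"].to_numpy(), config.efo_percentile))


def filter_quality(
    table: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, dict]:
    """Per-localization cfr/efo filter against multi-emitter contamination.

    Keeps rows with ``cfr <= cfr_max`` and ``efo <= efo cutoff``; row order is
    preserved.  Returns the filtered table and a report with the cutoff used
    and per-criterion removal counts.
    """
    cutoff = resolve_efo_cutoff(table, config)
    keep_cfr = table["cfr"] <= config.cfr_max
    keep_efo = table["efo"] <= cutoff
    keep = keep_cfr & keep_efo
    report = {
        "efo_cutoff_khz": cutoff,
        "n_in": int(len(table)),
        "removed_cfr": int((~keep_cfr).sum()),
        "removed_efo": int((~keep_efo).sum()),
        "n_kept": int(keep.sum()),
    }
    return table.loc[keep].reset_index(drop=True), report


def group_traces(table: pd.DataFrame) -> TraceSet:
    """Partition localizations into traces by TID (exact partition)."""
    return TraceSet(table)


def filter_traces(traces: TraceSet, config: FilterConfig) -> TraceSet:
    """Drop traces with < min_locs localizations or any-axis SD > max_axis_sd."""
    t = traces.table
    if len(t) == 0:
        return TraceSet(t)
    grp = t.groupby("tid")
    n = grp.size()
    sd = grp[list(_AXES)].std(ddof=1)
    # strict ">": a trace whose SD equals the bound exactly is kept; NaN SD
    # (single-localization traces) is handled by the count criterion alone
    too_spread = (sd > config.max_axis_sd).any(axis=1)
    keep_ids = n.index[(n >= config.min_locs) & ~too_spread]
    return TraceSet(t[t["tid"].isin(keep_ids)])


def trim_traces(traces: TraceSet, config: FilterConfig) -> TraceSet:
    """Remove the first ``trim_head`` localizations (time order) of each trace.

    Traces left with at least one localization are retained; traces fully
    consumed by the trim drop out.
    """
    t = traces.table
    if len(t) == 0:
        return TraceSet(t)
    pos = t.groupby("tid").cumcount()
    return TraceSet(t[pos >= config.trim_head])


def apply_z_scaling(traces: TraceSet, config: FilterConfig) -> TraceSet:
    """z <- z * z_scale for every localization; x and y are untouched."""
    t = traces.table.copy()
    t["z_nm"] = t["z_nm"] * config.z_scale
    return TraceSet(t)


def trace_centers(traces: TraceSet) -> pd.DataFrame:
    """Per-trace center of mass (unweighted mean of x, y, z) plus n_locs."""
    t = traces.table
    if len(t) == 0:
        return pd.DataFrame(columns=list(CENTER_COLUMNS)).astype(
            {"tid": np.int64, "n_locs": np.int64}
        )
    grp = t.groupby("tid")
    centers = grp[list(_AXES)].mean()
    centers["n_locs"] = grp.size()
    return centers.reset_index()


@dataclass
class FilterResult:
    """Output of the full filter cascade."""

    centers: pd.DataFrame
    localizations: pd.DataFrame  # surviving localizations, z-corrected
    report: dict


def run_filter_pipeline(table: pd.DataFrame, config: FilterConfig | None = None) -> FilterResult:
    """Run the cascade in the documented order and collect per-stage counts."""
    config = config or FilterConfig()
    filtered, quality_report = filter_quality(table, config)
    traces = group_traces(filtered)
    n_grouped = len(traces)
    traces = filter_traces(traces, config)
    n_after_trace_filter = len(traces)
    traces = trim_traces(traces, config)
    traces = apply_z_scaling(traces, config)
    centers = trace_centers(traces)
    report = {
        "quality": quality_report,
        "n_traces_grouped": n_grouped,
        "n_traces_after_filter": n_after_trace_filter,
        "n_traces_after_trim": len(traces),
        "n_centers": int(len(centers)),
        "config": dataclasses.asdict(config),
    }
    return FilterResult(centers=centers, localizations=traces.table, report=report)
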