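"""Conductometric dissolution analysis.

Raw conductivity traces are normalized per run to a 0-100% scale
(min-max over the analysis window) and the dissolution time is the
first sample reaching 90% of that range, censored at the experimental
window (default 60 s) when dissolution does not complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .crossing import first_crossing_index

__all__ = [
    "RunMetadata",
    "ConductivityTrace",
    "NormalizedTrace",
    "DissolutionResult",
    "NoSignalError",
    "load_traces",
    "smooth_trace",
    "normalize_trace",
    "dissolution_time",
    "batch_dissolution",
    "CONDITION_COLUMNS",
]

logger = logging.getLogger(__name__)

#: metadata columns that define an experimental condition (replicates share them)
CONDITION_COLUMNS = ("solvent", "viscosity_mPas", "rpm", "particle_class",
                     "temp_C", "compound", "vessel")


class NoSignalError(ValueError):
    """Raised when a trace carries no dynamic range to normalize."""


@dataclass
class RunMetadata:
    solvent: str | None = None
    viscosity_mPas: float | None = None
    rpm: float | None = None
    particle_class: str | None = None
    temp_C: float | None = None
    compound: str | None = None
    vessel: str | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        if self.viscosity_mPas is not None and not self.viscosity_mPas > 0:
            raise ValueError("viscosity must be positive")
        if self.rpm is not None and not self.rpm > 0:
            raise ValueError("rotor speed must be positive")

    def condition_key(self) -> tuple:
        return tuple(getattr(self, c) for c in CONDITION_COLUMNS)


@dataclass
class ConductivityTrace:
    """Raw conductivity readout versus time for one run."""

    times: np.ndarray
    values: np.ndarray
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValueError("trace needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class NormalizedTrace:
    """Per-run 0-100% standardized trace with its raw anchors."""

    times: np.ndarray
    values: np.ndarray
    raw_min: float
    raw_max: float
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite([self.raw_min, self.raw_max]).all() or self.raw_min >= self.raw_max:
            raise ValueError("anchors must be finite and distinct")


@dataclass
class DissolutionResult:
    """Dissolution time or incomplete-within-window flag for one run."""

    t90: float
    complete: bool
    window: float
    level: float
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def to_dict(self) -> dict:
        d = {"t90_s": round(float(self.t90), 6), "complete": bool(self.complete),
             "window_s": self.window, "level_percent": self.level}
        d.update({k: v for k, v in asdict(self.metadata).items() if v is not None})
        return d


def load_traces(path) -> list[ConductivityTrace]:
    """Read traces from a CSV with columns run_id, time_s, conductivity.

    Optional metadata columns (solvent, viscosity_mPas, rpm,
    particle_class, temp_C, compound, vessel) are attached per run.
    Rows are sorted by time; duplicate timestamps within a run are
    rejected.
    """
    df = pd.read_csv(path)
    required = {"run_id", "time_s", "conductivity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    for col in ("time_s", "conductivity"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")
        if df[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")

    traces = []
    for run_id, g in df.groupby("run_id", sort=True):
        if g["time_s"].duplicated().any():
            raise ValueError(f"duplicate timestamps in run {run_id!r}")
        if not g["time_s"].is_monotonic_increasing:
            logger.info("run %r: rows not time-sorted, sorting", run_id)
            g = g.sort_values("time_s")
        meta_kwargs = {"replicate": str(run_id)}
        for col in CONDITION_COLUMNS:
            if col in g.columns:
                meta_kwargs[col] = g[col].iloc[0]
        traces.append(ConductivityTrace(times=g["time_s"].to_numpy(),
                                        values=g["conductivity"].to_numpy(),
                                        metadata=RunMetadata(**meta_kwargs)))
    if not traces:
        raise ValueError("no runs found in input")
    return traces


def smooth_trace(trace: ConductivityTrace, window_samples: int = 1) -> ConductivityTrace:
    """Centered moving-median smoothing; endpoints use shrinking windows.

    ``window_samples`` must be odd; 1 is the identity.
    """
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window_samples == 1:
        return trace
    half = window_samples // 2
    v = trace.values
    out = np.empty_like(v)
    for i in range(len(v)):
        lo = max(0, i - half)
        out[i] = np.median(v[lo:i + half + 1])
    return ConductivityTrace(times=trace.times.copy(), values=out,
                             metadata=trace.metadata)


def normalize_trace(trace: ConductivityTrace,
                    window: float | None = None) -> NormalizedTrace:
    """Min-max standardize a run to 0-100%.

    Anchors are the min and max of the trace within the analysis window
    (first ``window`` seconds from the first sample; whole trace if None).
    """
    if window is not None:
        sel = trace.times <= trace.times[0] + window
        sub = trace.values[sel]
    else:
        sub = trace.values
    vmin, vmax = float(sub.min()), float(sub.max())
    if vmax <= vmin:
        raise NoSignalError("constant trace: no dynamic range to normalize")
    norm = 100.0 * (trace.values - vmin) / (vmax - vmin)
    return NormalizedTrace(times=trace.times.copy(), values=norm,
                           raw_min=vmin, raw_max=vmax, metadata=trace.metadata)


def dissolution_time(ntrace: NormalizedTrace, level: float = 90.0,
                     window: float = 60.0) -> DissolutionResult:
    """First sample reaching ``level`` percent within the window.

    The window is measured from the first sample. If the level is never
    reached inside the window the result is incomplete, carrying the
    window length as a censoring time.
    """
    if not 0 < level <= 100:
        raise ValueError("level must be in (0, 100]")
    if window <= 0:
        raise ValueError("window must be positive")
    t_rel = ntrace.times - ntrace.times[0]
    in_window = t_rel <= window
    idx = first_crossing_index(np.where(in_window, ntrace.values, -np.inf), level)
    if idx is None:
        return DissolutionResult(t90=window, complete=False, window=window,
                                 level=level, metadata=ntrace.metadata)
    return DissolutionResult(t90=float(t_rel[idx]), complete=True,
                             window=window, level=level, metadata=ntrace.metadata)


def batch_dissolution(traces: list[ConductivityTrace], level: float = 90.0,
                      window: float = 60.0, smooth_window: int = 1
                      ) -> tuple[list[DissolutionResult], pd.DataFrame]:
    """Dissolution times for many runs plus a per-condition summary.

    Replicates (runs sharing all condition metadata) are summarized as
    mean +/- sample SD of t90 over *complete* runs only; incomplete runs
    are counted separately, never silently averaged in.
    """
    if not traces:
        raise ValueError("no traces given")
    results = []
    for tr in traces:
        tr = smooth_trace(tr, smooth_window)
        # anchors over the whole recorded trace: a plateau reached after
        # the censoring window must still define 100%, otherwise slow
        # dissolutions would always look complete
        nt = normalize_trace(tr)
        results.append(dissolution_time(nt, level=level, window=window))

    rows = []
    by_condition: dict[tuple, list[DissolutionResult]] = {}
    for res in results:
        by_condition.setdefault(res.metadata.condition_key(), []).append(res)
    for key, group in sorted(by_condition.items(), key=lambda kv: str(kv[0])):
        complete = [r.t90 for r in group if r.complete]
        row = dict(zip(CONDITION_COLUMNS, key))
        row.update({
            "n": len(group),
            "n_complete": len(complete),
            "n_incomplete": len(group) - len(complete),
            "mean_t90_s": float(np.mean(complete)) if complete else np.nan,
            "sd_t90_s": float(np.std(complete, ddof=1)) if len(complete) > 1 else np.nan,
        })
        rows.append(row)
    summary = pd.DataFrame(rows)
    return results, summary
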