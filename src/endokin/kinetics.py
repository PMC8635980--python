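"""Trace normalization, Rab-conversion event detection, event-anchored
alignment and ensemble averaging, accessory-pattern classification, and the
cell-growth doubling time.

Endosome maturation is asynchronous: each endosome converts from Rab5 to
Rab7 at its own wall-clock time.  Traces are therefore background-corrected,
min-max normalized over the full recorded kinetic (range 0 to 1), anchored
at a per-endosome reference event — the Rab5 peak, or the time Rab7 reaches
50% of its final maximum (the point of Rab conversion) — and averaged on the
resulting relative-time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, medfilt

__all__ = [
    "KineticTrace",
    "ReferenceEvent",
    "AlignedEnsemble",
    "GrowthObservation",
    "PatternParams",
    "DegenerateTraceError",
    "NoConversionError",
    "trace_from_table",
    "normalize_trace",
    "detect_rab5_peak",
    "detect_rab7_halfmax",
    "detect_onset",
    "align_and_average",
    "conversion_duration",
    "classify_pattern",
    "doubling_time",
]


class DegenerateTraceError(ValueError):
    """Raised for constant traces that cannot be min-max normalized."""


class NoConversionError(ValueError):
    """Raised when no durable Rab7 half-max crossing exists."""


# ---------------------------------------------------------------------------
# Traces and normalization
# ---------------------------------------------------------------------------

@dataclass
class KineticTrace:
    """One endosome x channel kinetic.

    ``raw`` is the background-subtracted rim MFI (may be negative after
    subtraction); ``norm`` is min-max normalized over the entire kinetic so
    0 and 1 are both attained.  ``relative_time_min`` is populated once an
    alignment event is applied.
    """

    endosome_id: str
    channel: str
    time_min: np.ndarray
    raw: np.ndarray
    norm: np.ndarray | None = None
    relative_time_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.time_min.shape != self.raw.shape:
            raise ValueError("time and value vectors differ in length")
        if self.time_min.ndim != 1:
            raise ValueError("trace vectors must be 1-D")
        if len(self.time_min) and (np.diff(self.time_min) <= 0).any():
            raise ValueError("time vector must be strictly increasing")


@dataclass(frozen=True)
class ReferenceEvent:
    """Per-endosome alignment anchor set to relative time t = 0."""

    endosome_id: str
    mode: Literal["rab5_peak", "rab7_halfmax"]
    t_ref_min: float
    truncated: bool = False  # peak at first/last frame: possibly clipped
    peak_count: int | None = None


def trace_from_table(table: pd.DataFrame, endosome_id: str,
                     channel: str) -> KineticTrace:
    """Build a background-subtracted raw trace from a measured trace table."""
    sel = table[(table.endosome_id == endosome_id)
                & (table.channel == channel)].sort_values("frame")
    if sel.empty:
        raise ValueError(f"no rows for endosome {endosome_id!r} channel "
                         f"{channel!r}")
    raw = sel.rim_mfi.to_numpy(float) - sel.bg_mfi.to_numpy(float)
    return KineticTrace(endosome_id, channel, sel.time_min.to_numpy(float),
                        raw)


def normalize_trace(trace: KineticTrace) -> KineticTrace:
    """Min-max normalize over the full kinetic to the range [0, 1].

    Both bounds are attained by construction; normalization is idempotent.
    """
    if len(trace.raw) < 3:
        raise ValueError("need at least 3 time points to normalize")
    lo, hi = float(trace.raw.min()), float(trace.raw.max())
    if hi <= lo:
        raise DegenerateTraceError(
            f"degenerate trace for {trace.endosome_id}/{trace.channel}: "
            f"constant value {lo}"
        )
    return replace(trace, norm=(trace.raw - lo) / (hi - lo))


def _require_norm(trace: KineticTrace) -> np.ndarray:
    if trace.norm is None:
        raise ValueError("trace must be normalized first")
    return trace.norm


# ---------------------------------------------------------------------------
# Reference events
# ---------------------------------------------------------------------------

def detect_rab5_peak(trace: KineticTrace,
                     median_filter: bool = False) -> ReferenceEvent:
    """Anchor at the Rab5 peak: time of the global maximum of the normalized
    trace (earliest sample on ties; the tallest peak for multi-peak traces).

    A maximum at the first or last frame is flagged as possibly truncated.
    An optional 3-point median filter guards detection on noisy traces; it
    never alters the stored trace.
    """
    y = _require_norm(trace)
    z = medfilt(y, 3) if median_filter else y
    i = int(np.argmax(z))
    peaks, _ = find_peaks(np.concatenate([[-np.inf], z, [-np.inf]]),
                          prominence=0.2)
    if i in (0, len(z) - 1):
        warnings.warn(
            f"{trace.endosome_id}/{trace.channel}: maximum at trace edge "
            "(possible truncated event)", stacklevel=2)
    return ReferenceEvent(trace.endosome_id, "rab5_peak",
                          float(trace.time_min[i]),
                          truncated=i in (0, len(z) - 1),
                          peak_count=max(len(peaks), 1))


def _last_dip_crossing(t: np.ndarray, y: np.ndarray,
                       level: float) -> float | None:
    """Earliest upward crossing of ``level`` after which y never falls below
    it again; linearly interpolated.  None if no such crossing."""
    if y[0] >= level and (y >= level).all():
        return None  # already above: no upward crossing to anchor on
    below = np.flatnonzero(y < level)
    if len(below) == 0 or below[-1] == len(y) - 1:
        return None
    i = below[-1]  # last sample below the level
    y0, y1 = y[i], y[i + 1]
    return float(t[i] + (level - y0) / (y1 - y0) * (t[i + 1] - t[i]))


def detect_rab7_halfmax(trace: KineticTrace, level: float = 0.5,
                        plateau_quantile: float = 0.75,
                        plateau_min: float = 0.8,
                        median_filter: bool = False) -> ReferenceEvent:
    """Anchor at Rab conversion: the earliest upward crossing of 50% of the
    final maximum after which the trace never falls below it again.

    Requires a plateau (mean of the last quartile of the normalized trace
    >= ``plateau_min``); the crossing time is linearly interpolated between
    frames.
    """
    y = _require_norm(trace)
    z = medfilt(y, 3) if median_filter else y
    tail = z[int(np.floor(plateau_quantile * len(z))):]
    if len(tail) == 0 or tail.mean() < plateau_min:
        raise NoConversionError(
            f"no conversion detected for {trace.endosome_id}/"
            f"{trace.channel}: no stable plateau (last-quartile mean "
            f"{tail.mean() if len(tail) else float('nan'):.2f} < "
            f"{plateau_min})"
        )
    t_ref = _last_dip_crossing(trace.time_min, z, level)
    if t_ref is None:
        raise NoConversionError(
            f"no conversion detected for {trace.endosome_id}/"
            f"{trace.channel}: no durable upward crossing of {level}"
        )
    return ReferenceEvent(trace.endosome_id, "rab7_halfmax", t_ref)


def detect_onset(trace: KineticTrace, level: float = 0.1) -> float:
    """First interpolated upward crossing of ``level`` on the way to the
    global maximum (recruitment onset)."""
    y = _require_norm(trace)
    imax = int(np.argmax(y))
    seg = y[:imax + 1]
    above = np.flatnonzero(seg >= level)
    if len(above) == 0:
        raise ValueError("trace never reaches the onset level before its "
                         "maximum")
    j = above[0]
    if j == 0:
        return float(trace.time_min[0])
    t = trace.time_min
    return float(t[j - 1] + (level - y[j - 1]) / (y[j] - y[j - 1])
                 * (t[j] - t[j - 1]))


# ---------------------------------------------------------------------------
# Alignment and averaging
# ---------------------------------------------------------------------------

@dataclass
class AlignedEnsemble:
    """Per-bin ensemble statistics on the relative-time axis.

    ``table`` columns: relative_time_min, channel, mean, sd, sem, n.
    SD uses the sample estimator (ddof=1, 0 for a single value);
    sem = sd / sqrt(n).  Bins carried by fewer than ``n_min`` endosomes are
    excluded.
    """

    table: pd.DataFrame
    bin_width_min: float
    n_endosomes: int

    def value_at(self, channel: str, relative_time_min: float,
                 stat: str = "mean") -> float:
        sel = self.table[(self.table.channel == channel)
                         & np.isclose(self.table.relative_time_min,
                                      relative_time_min)]
        if sel.empty:
            raise KeyError(f"no bin at t={relative_time_min} for "
                           f"channel {channel!r}")
        return float(sel.iloc[0][stat])


def align_and_average(traces: Sequence[KineticTrace],
                      events: Iterable[ReferenceEvent],
                      bin_width_min: float | None = None,
                      n_min: int = 2,
                      use: str = "norm") -> AlignedEnsemble:
    """Align traces at their per-endosome reference events and average.

    Each sample is assigned to the nearest multiple of ``bin_width_min`` of
    its relative time (time - t_ref); per bin and channel the mean, SD, SEM
    and count are reported.  Alignment is shift-equivariant: adding a common
    offset to a trace's times and its t_ref changes nothing.
    """
    traces = list(traces)
    ev_map = {e.endosome_id: e for e in events}
    ids = {t.endosome_id for t in traces}
    missing = ids - set(ev_map)
    if missing:
        raise ValueError(f"no reference event for endosomes {sorted(missing)}")
    if len(ids) < 2:
        raise ValueError("need at least 2 endosomes to average")
    if bin_width_min is None:
        intervals = [np.diff(t.time_min).min() for t in traces
                     if len(t.time_min) > 1]
        bin_width_min = float(np.median(intervals))
    if bin_width_min <= 0:
        raise ValueError("bin width must be > 0")

    rows = []
    for tr in traces:
        vals = _require_norm(tr) if use == "norm" else tr.raw
        rel = tr.time_min - ev_map[tr.endosome_id].t_ref_min
        tr.relative_time_min = rel
        bins = np.round(rel / bin_width_min) * bin_width_min
        for b, v in zip(bins, vals):
            rows.append((tr.endosome_id, tr.channel, b, v))
    df = pd.DataFrame(rows, columns=["endosome_id", "channel",
                                     "relative_time_min", "value"])
    # one value per endosome per bin (multiple samples in a bin: average
    # within the endosome first, so each endosome carries equal weight)
    per_endo = (df.groupby(["channel", "relative_time_min", "endosome_id"],
                           sort=True)["value"].mean().reset_index())
    def _sd(v):
        # exact zero for constant bins (identical traces must give sd 0)
        if len(v) < 2 or v.max() == v.min():
            return 0.0
        return v.std(ddof=1)

    g = per_endo.groupby(["channel", "relative_time_min"], sort=True)["value"]
    out = g.agg(mean="mean", sd=_sd, n="size").reset_index()
    out["sd"] = out["sd"].astype(float)
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out = out[out["n"] >= n_min].reset_index(drop=True)
    out["relative_time_min"] = np.where(
        np.abs(out["relative_time_min"]) < 1e-12, 0.0,
        out["relative_time_min"])
    return AlignedEnsemble(out[["relative_time_min", "channel", "mean",
                                "sd", "sem", "n"]],
                           bin_width_min, len(ids))


# ---------------------------------------------------------------------------
# Conversion duration
# ---------------------------------------------------------------------------

def _first_rise_crossing(t: np.ndarray, y: np.ndarray,
                         level: float) -> float | None:
    """First interpolated upward crossing of ``level``."""
    above = np.flatnonzero(y > level)
    if len(above) == 0:
        return None
    j = above[0]
    if j == 0:
        return float(t[0])
    return float(t[j - 1] + (level - y[j - 1]) / (y[j] - y[j - 1])
                 * (t[j] - t[j - 1]))


def conversion_duration(rab5_trace: KineticTrace, rab7_trace: KineticTrace,
                        lo: float = 0.1, hi: float = 0.1) -> float:
    """Duration of Rab conversion, in minutes.

    Measured from the time normalized Rab7 first exceeds ``lo`` (fraction of
    its plateau) to the time normalized Rab5 last falls below ``hi`` and
    stays below; both crossings linearly interpolated.
    """
    if rab5_trace.endosome_id != rab7_trace.endosome_id:
        raise ValueError("traces come from different endosomes")
    y5, y7 = _require_norm(rab5_trace), _require_norm(rab7_trace)
    t5, t7 = rab5_trace.time_min, rab7_trace.time_min

    t_start = _first_rise_crossing(t7, y7, lo)
    if t_start is None:
        raise NoConversionError(
            f"{rab7_trace.endosome_id}: Rab7 never exceeds {lo} of plateau")

    above = np.flatnonzero(y5 >= hi)
    if len(above) == 0:
        raise ValueError(f"{rab5_trace.endosome_id}: Rab5 never reaches {hi}")
    i = above[-1]
    if i == len(y5) - 1:
        raise ValueError(
            f"conversion incomplete for {rab5_trace.endosome_id}: Rab5 "
            f"never falls below {hi} and stays below")
    t_end = float(t5[i] + (hi - y5[i]) / (y5[i + 1] - y5[i])
                  * (t5[i + 1] - t5[i]))
    return t_end - t_start


# ---------------------------------------------------------------------------
# Accessory-marker pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternParams:
    """Deterministic stand-in for by-eye pattern binning.

    Peaks count when their prominence is at least ``prominence_min`` and
    they are separated by at least ``separation_min`` minutes; a trace is
    "persistent" when it stays at or above ``persist_level`` for at least
    ``persist_fraction`` of the frames later than ``grace_min`` minutes
    after the conversion reference.
    """

    prominence_min: float = 0.2
    separation_min: float = 3.0
    persist_level: float = 0.3
    persist_fraction: float = 0.8
    grace_min: float = 5.0


def classify_pattern(trace: KineticTrace, event: ReferenceEvent,
                     params: PatternParams = PatternParams()) -> str:
    """Bin an accessory-marker kinetic into single_peak / double_peak /
    persistent, relative to the conversion reference event."""
    y = _require_norm(trace)
    t = trace.time_min
    if t[-1] < event.t_ref_min + params.grace_min:
        raise ValueError(
            f"unclassifiable: trace for {trace.endosome_id} ends at "
            f"{t[-1]:.1f} min, before t_ref + grace "
            f"({event.t_ref_min + params.grace_min:.1f} min)")

    late = y[t >= event.t_ref_min + params.grace_min]
    if len(late) and np.mean(late >= params.persist_level) \
            >= params.persist_fraction:
        return "persistent"

    dt = float(np.median(np.diff(t)))
    distance = max(int(np.ceil(params.separation_min / dt)), 1)
    padded = np.concatenate([[y.min()], y, [y.min()]])
    peaks, _ = find_peaks(padded, prominence=params.prominence_min,
                          distance=distance)
    return "double_peak" if len(peaks) >= 2 else "single_peak"


# ---------------------------------------------------------------------------
# Cell growth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthObservation:
    """Two cell counts c1, c2 at times t1 < t2 (hours)."""

    c1: float
    c2: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("cell counts must be positive")
        if self.t2 <= self.t1:
            raise ValueError("t2 must exceed t1")


def doubling_time(obs: GrowthObservation) -> float:
    """Exponential-growth doubling time (t2 - t1) * log 2 / log(c2 / c1),
    in hours.  Declining counts yield a negative value with a warning."""
    if obs.c2 == obs.c1:
        raise ValueError("no growth: c2 equals c1")
    td = (obs.t2 - obs.t1) * np.log(2.0) / np.log(obs.c2 / obs.c1)
    if obs.c2 < obs.c1:
        warnings.warn("cell count declined: doubling time is negative",
                      stacklevel=2)
    return float(td)
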