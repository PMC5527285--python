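"""Nuclear-envelope rupture detection from dual-reporter time series.

A cell co-expresses a nuclear reporter (NLS-tagged, e.g. mCherry-NLS) and a
cytoplasmic reporter (NES-tagged, e.g. AcGFP-NES).  While the envelope is
intact the NLS reporter is enriched in the nucleus, so the nuclear-to-
cytoplasmic intensity ratio R(t) sits at a per-cell baseline well above 1.
When the envelope ruptures, both reporters equilibrate across the two
compartments within a frame or two: R collapses towards 1 (efflux of the NLS
reporter) while the NES reporter floods into the nucleus (influx).  After
the envelope reseals, active import re-accumulates the NLS reporter and R
climbs back to baseline.

The detector works entirely on ratios relative to the per-cell baseline, so
it is insensitive to illumination and expression-level differences:

* event start  - first frame where R drops below ``baseline*(1 - d_min)``
  after a sudden fall (>= ``d_step*baseline`` within ``window`` frames);
* event end    - first frame after the event minimum at which R has risen
  for ``recovery_frames`` consecutive frames, i.e. nuclear re-accumulation
  has begun;
* frames flagged as mitotic (envelope breakdown is physiological there) veto
  any overlapping event;
* an NES-influx cross-check marks events seen in both channels.

Events still open when the recording stops are flagged ``truncated`` and are
excluded from duration statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = [
    "ReporterTrace",
    "RuptureEvent",
    "EventSummary",
    "DetectionParams",
    "compute_ratio_trace",
    "detect_rupture_events",
    "cohort_event_summary",
    "traces_from_dataframe",
    "events_to_dataframe",
]


@dataclass
class ReporterTrace:
    """Per-cell time series of nuclear/cytoplasmic reporter intensities.

    ``time`` is a strictly increasing uniform grid in minutes with at least
    5 frames; intensities are arbitrary units, non-negative.
    """

    cell_id: object
    time: np.ndarray
    nls_nuc: np.ndarray
    nls_cyt: np.ndarray
    nes_nuc: np.ndarray
    nes_cyt: np.ndarray
    mitosis: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        for name in ("nls_nuc", "nls_cyt", "nes_nuc", "nes_cyt"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} length does not match time grid")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative intensities")
            setattr(self, name, arr)
        if self.mitosis is None:
            self.mitosis = np.zeros(self.time.shape, bool)
        else:
            self.mitosis = np.asarray(self.mitosis, bool)
            if self.mitosis.shape != self.time.shape:
                raise ValueError("mitosis flags do not match time grid")
        if self.time.size < 5:
            raise ValueError("trace needs at least 5 frames")
        steps = np.diff(self.time)
        if (steps <= 0).any():
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return int(self.time.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "time_min": self.time,
                "nls_nuc": self.nls_nuc,
                "nls_cyt": self.nls_cyt,
                "nes_nuc": self.nes_nuc,
                "nes_cyt": self.nes_cyt,
                "mitosis_flag": self.mitosis.astype(int),
            }
        )


def traces_from_dataframe(df: pd.DataFrame) -> list[ReporterTrace]:
    """Rebuild :class:`ReporterTrace` objects from a long-format table."""
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("time_min")
        traces.append(
            ReporterTrace(
                cell_id=cell_id,
                time=sub["time_min"].to_numpy(),
                nls_nuc=sub["nls_nuc"].to_numpy(),
                nls_cyt=sub["nls_cyt"].to_numpy(),
                nes_nuc=sub["nes_nuc"].to_numpy(),
                nes_cyt=sub["nes_cyt"].to_numpy(),
                mitosis=sub["mitosis_flag"].to_numpy().astype(bool),
            )
        )
    return traces


@dataclass(frozen=True)
class RuptureEvent:
    """One detected envelope-rupture episode (times in minutes)."""

    cell_id: object
    start: float
    end: float
    depth: float
    crossvalidated: bool = False
    truncated: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class EventSummary:
    n_cells: int
    observation_time_h: float  # per cell
    n_events: int
    events_per_cell_hour: float
    mean_duration_min: float | None
    n_truncated: int = 0


@dataclass(frozen=True)
class DetectionParams:
    """Detector thresholds, all relative to the per-cell ratio baseline.

    d_min
        an event frame sits below ``baseline*(1 - d_min)``.
    d_step
        "sudden": the drop into the event spans >= ``d_step*baseline``
        within ``window`` frames.
    recovery_frames
        consecutive rising frames that mark nuclear re-accumulation.
    min_recovery_frac
        the rise must also lift the ratio above the event minimum by this
        fraction of the event depth, so plateau noise cannot end an event
        that genuine re-import has not yet begun to close.
    merge_frames
        events separated by at most this many frames are merged.
    mitosis_pad
        frames of padding around mitosis flags when vetoing events.
    nes_factor
        NES-influx cross-check: nuclear NES must exceed this multiple of
        its out-of-event baseline inside the event window.
    """

    d_min: float = 0.4
    d_step: float = 0.25
    window: int = 2
    recovery_frames: int = 2
    min_recovery_frac: float = 0.1
    merge_frames: int = 2
    mitosis_pad: int = 2
    nes_factor: float = 1.2
    median_smooth: bool = True


def compute_ratio_trace(
    trace: ReporterTrace,
    median_smooth: bool = True,
    d_min: float = 0.4,
) -> tuple[np.ndarray, float]:
    """NLS nuclear/cytoplasmic ratio series and its per-cell baseline.

    The ratio is optionally 3-frame median filtered.  The baseline is a
    two-pass median: frames more than ``d_min`` below the first-pass median
    are treated as candidate event frames and excluded from the second pass.
    """
    nuc, cyt = trace.nls_nuc, trace.nls_cyt
    if median_smooth:
        nuc = medfilt(nuc, 3)
        cyt = medfilt(cyt, 3)
    if (cyt <= 0).any():
        raise ValueError("cytoplasmic NLS intensity is <= 0 after smoothing")
    ratio = nuc / cyt
    first = float(np.median(ratio))
    keep = ratio >= first * (1.0 - d_min)
    baseline = float(np.median(ratio[keep])) if keep.any() else first
    return ratio, baseline


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks], idx[-1]]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_rupture_events(
    trace: ReporterTrace, params: DetectionParams | None = None
) -> list[RuptureEvent]:
    """Detect rupture events in one trace.  Zero events is a valid result."""
    p = params or DetectionParams()
    ratio, baseline = compute_ratio_trace(trace, p.median_smooth, p.d_min)
    n = ratio.size
    below = ratio < baseline * (1.0 - p.d_min)

    raw: list[tuple[int, int, bool]] = []  # (start_idx, end_idx, truncated)
    for run_start, run_stop in _runs(below):
        # "sudden": the entry frame must follow a steep drop
        lo = max(0, run_start - p.window)
        prev_max = ratio[lo:run_start].max() if run_start > lo else ratio[run_start]
        if prev_max - ratio[run_start] < p.d_step * baseline and run_start > 0:
            continue
        if run_start == 0:
            # trace starts inside a low-ratio state: cannot certify suddenness
            continue
        min_idx = run_start + int(np.argmin(ratio[run_start : run_stop + 1]))
        r_min = ratio[min_idx]
        rise_floor = r_min + p.min_recovery_frac * (baseline - r_min)
        end_idx, truncated = None, False
        m = p.recovery_frames
        for e in range(min_idx + m, n):
            window = ratio[e - m : e + 1]
            if np.all(np.diff(window) > 0) and ratio[e] >= rise_floor:
                end_idx = e
                break
        if end_idx is None:
            end_idx, truncated = n - 1, True
        raw.append((run_start, end_idx, truncated))

    # merge events separated by <= merge_frames
    merged: list[list] = []
    for s, e, tr in sorted(raw):
        if merged and s - merged[-1][1] <= p.merge_frames:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = tr
        else:
            merged.append([s, e, tr])

    # veto events overlapping (padded) mitosis windows
    mito = trace.mitosis.copy()
    if mito.any() and p.mitosis_pad > 0:
        idx = np.flatnonzero(mito)
        for i in idx:
            mito[max(0, i - p.mitosis_pad) : i + p.mitosis_pad + 1] = True

    # NES baseline from out-of-event frames
    in_event = np.zeros(n, bool)
    for s, e, _ in merged:
        in_event[s : e + 1] = True
    nes = trace.nes_nuc
    nes_base = float(np.median(nes[~in_event])) if (~in_event).any() else float(np.median(nes))

    events: list[RuptureEvent] = []
    for s, e, tr in merged:
        if mito[s : e + 1].any():
            continue
        depth = (baseline - float(ratio[s : e + 1].min())) / baseline
        depth = float(min(max(depth, 1e-12), 1.0))
        cross = bool(nes_base > 0 and nes[s : e + 1].max() >= p.nes_factor * nes_base)
        events.append(
            RuptureEvent(
                cell_id=trace.cell_id,
                start=float(trace.time[s]),
                end=float(trace.time[e]),
                depth=depth,
                crossvalidated=cross,
                truncated=tr,
            )
        )
    return events


def cohort_event_summary(
    traces: Sequence[ReporterTrace], events: Iterable[RuptureEvent]
) -> EventSummary:
    """Aggregate counts, per-cell-hour rate and mean (non-truncated) duration."""
    traces = list(traces)
    if not traces:
        raise ValueError("empty trace set")
    events = list(events)
    ids = {t.cell_id for t in traces}
    for ev in events:
        if ev.cell_id not in ids:
            raise ValueError(f"event for unknown cell {ev.cell_id!r}")
    cell_hours = sum((t.time[-1] - t.time[0]) / 60.0 for t in traces)
    obs_h = cell_hours / len(traces)
    complete = [ev for ev in events if not ev.truncated]
    mean_dur = float(np.mean([ev.duration for ev in complete])) if complete else None
    return EventSummary(
        n_cells=len(traces),
        observation_time_h=float(obs_h),
        n_events=len(events),
        events_per_cell_hour=float(len(events) / cell_hours) if cell_hours else 0.0,
        mean_duration_min=mean_dur,
        n_truncated=len(events) - len(complete),
    )


def events_to_dataframe(events: Iterable[RuptureEvent]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": ev.cell_id,
            "start_min": ev.start,
            "end_min": ev.end,
            "duration_min": ev.duration,
            "depth": ev.depth,
            "crossvalidated": ev.crossvalidated,
            "truncated": ev.truncated,
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "start_min",
            "end_min",
            "duration_min",
            "depth",
            "crossvalidated",
            "truncated",
        ],
    )
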