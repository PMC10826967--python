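"""Voltage-event detection, classification, conversion, and synchrony.

A depolarization *event* spans from an upward crossing of ``v_on`` to
the next downward crossing of ``v_off`` (hysteresis, ``v_on > v_off``,
so the small oscillations riding on a burst plateau do not split one
event into many).  Within an event the number of local voltage maxima
(prominence >= 2 mV) distinguishes single spikes from k-spike bursts.
Event taxonomy:

``spike``
    one supra-threshold peak;
``doublet``
    two single-peak events in rapid succession (the voltage re-crosses
    ``v_off`` between peaks, gap < 40 ms) merged into one event;
``k-spike burst``
    k >= 2 peaks inside one continuous supra-threshold envelope;
``long burst``
    a burst lasting > 1.5x the median burst duration of its train.

A cell counts as *converted to bursting* when at least half of its
classified events are bursts.  Network synchrony is scored as the mean
pairwise Pearson correlation of the cells' slow Ca2+ time courses
(burst-envelope-level coordination, the quantity Ca2+-imaging studies
report); voltage-trace correlation is available via ``signal="v"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .netsim import ClampProtocol, Trajectory

__all__ = [
    "Event",
    "EventTrain",
    "detect_events",
    "classify_event",
    "classify_events",
    "event_train",
    "is_converted_burster",
    "minimal_period",
    "synchrony_index",
    "active_phase_windows",
    "clamp_protocol_from_trace",
    "event_trains_to_frame",
]

V_ON_DEFAULT = -35.0   # mV, upward (event start) threshold
V_OFF_DEFAULT = -45.0  # mV, downward (event end) threshold
PROMINENCE_DEFAULT = 2.0  # mV, peak prominence within an event
DOUBLET_GAP_MS = 40.0  # max sub-threshold gap between doublet partners
LONG_BURST_FACTOR = 1.5  # x median burst duration


@dataclass(frozen=True)
class Event:
    """One supra-threshold depolarization event."""

    t_start: float
    t_end: float
    n_peaks: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("event must have positive duration")
        if self.n_peaks < 1:
            raise ValueError("an event contains at least one peak")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class EventTrain:
    """Ordered classified events of one cell over an analysis window."""

    cell: int
    events: tuple
    window: tuple

    def __post_init__(self) -> None:
        prev = -np.inf
        for e in self.events:
            if e.t_start < prev:
                raise ValueError("events must be time-ordered, non-overlapping")
            prev = e.t_end

    @property
    def labels(self) -> list:
        return [e.label for e in self.events]

    @property
    def burst_fraction(self) -> Optional[float]:
        """Fraction of events labelled as bursts; None for an empty train."""
        if not self.events:
            return None
        n_burst = sum(1 for e in self.events if e.label and "burst" in e.label)
        return n_burst / len(self.events)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_events(
    v: np.ndarray,
    dt: float,
    v_on: float = V_ON_DEFAULT,
    v_off: float = V_OFF_DEFAULT,
    prominence: float = PROMINENCE_DEFAULT,
    t0: float = 0.0,
) -> List[Event]:
    """Hysteresis event detector on a single voltage trace.

    An event opens when V crosses ``v_on`` upward and closes at the next
    downward crossing of ``v_off``; an event still open at the end of
    the trace is discarded (only complete events are classified).
    """
    if v_on <= v_off:
        raise ValueError("hysteresis requires v_on > v_off")
    v = np.asarray(v, dtype=float)
    ups = np.where((v[:-1] < v_on) & (v[1:] >= v_on))[0] + 1
    downs = np.where((v[:-1] >= v_off) & (v[1:] < v_off))[0] + 1
    events: List[Event] = []
    last_end = -1
    for u in ups:
        if u <= last_end:
            continue  # still inside the previous event
        after = downs[downs > u]
        if after.size == 0:
            break
        d = int(after[0])
        seg = v[max(u - 1, 0): d + 1]
        peaks, _ = find_peaks(seg, prominence=prominence)
        events.append(
            Event(
                t_start=t0 + u * dt,
                t_end=t0 + d * dt,
                n_peaks=max(len(peaks), 1),
            )
        )
        last_end = d
    return events


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _merge_doublets(events: Sequence[Event]) -> List[Event]:
    merged: List[Event] = []
    i = 0
    while i < len(events):
        e = events[i]
        if (
            e.n_peaks == 1
            and i + 1 < len(events)
            and events[i + 1].n_peaks == 1
            and events[i + 1].t_start - e.t_end < DOUBLET_GAP_MS
        ):
            nxt = events[i + 1]
            merged.append(
                Event(e.t_start, nxt.t_end, n_peaks=2, label="doublet")
            )
            i += 2
        else:
            merged.append(e)
            i += 1
    return merged


def classify_event(e: Event) -> str:
    """Label one event from its peak count (no train context)."""
    return "spike" if e.n_peaks == 1 else f"{e.n_peaks}-spike burst"


def classify_events(events: Sequence[Event]) -> List[Event]:
    """Classify a whole train: merge doublets, label bursts, flag long bursts.

    The "long burst" relabel needs the train context (its median burst
    duration), which is why classification is train-level.
    """
    merged = _merge_doublets(list(events))
    out = [
        e if e.label else replace(e, label=classify_event(e)) for e in merged
    ]
    burst_durations = [e.duration for e in out if e.label.endswith("burst")]
    if burst_durations:
        cutoff = LONG_BURST_FACTOR * float(np.median(burst_durations))
        out = [
            replace(e, label="long burst")
            if e.label.endswith("burst") and e.label != "doublet" and e.duration > cutoff
            else e
            for e in out
        ]
    return out


def event_train(
    traj_or_v,
    cell: int = 0,
    dt: Optional[float] = None,
    window: Optional[tuple] = None,
    **detect_kwargs,
) -> EventTrain:
    """Detect + classify events for one cell of a trajectory (or raw trace)."""
    if isinstance(traj_or_v, Trajectory):
        traj = traj_or_v.window(*window) if window else traj_or_v.window()
        v = traj.v[cell]
        dt = traj.dt
        t0 = float(traj.times[0])
        window = (float(traj.times[0]), float(traj.times[-1]))
    else:
        if dt is None:
            raise ValueError("dt is required for a raw voltage trace")
        v = np.asarray(traj_or_v, dtype=float)
        t0 = window[0] if window else 0.0
        window = window or (0.0, dt * (len(v) - 1))
    evs = classify_events(detect_events(v, dt, t0=t0, **detect_kwargs))
    return EventTrain(cell=cell, events=tuple(evs), window=window)


def is_converted_burster(train: EventTrain) -> tuple:
    """(converted?, burst fraction): converted iff >= 50% of events are bursts.

    Doublets — pairs of separate spikes in rapid succession — do not
    count as bursts.  An empty train yields (None, nan).
    """
    frac = train.burst_fraction
    if frac is None:
        return None, float("nan")
    return frac >= 0.5, frac


# ---------------------------------------------------------------------------
# Periodicity and synchrony
# ---------------------------------------------------------------------------

def minimal_period(symbols: Sequence[str]) -> Optional[int]:
    """Smallest k such that the label sequence is k-periodic; None if aperiodic.

    Exact symbol matching over the whole window; at least two full
    repeats must fit, so k <= len(symbols) // 2.
    """
    symbols = list(symbols)
    n = len(symbols)
    for k in range(1, n // 2 + 1):
        if all(symbols[i] == symbols[i + k] for i in range(n - k)):
            return k
    return None


def synchrony_index(
    traj: Trajectory,
    window: Optional[tuple] = None,
    signal: str = "c",
) -> float:
    """Mean pairwise Pearson correlation across cells; in [-1, 1].

    Measured on the slow Ca2+ traces by default, so the index scores
    burst-envelope coordination (as Ca2+-imaging studies do) and is
    insensitive to millisecond-scale spike lags between entrained
    cells; pass ``signal="v"`` for raw voltage correlation.  Cells with
    constant traces are excluded with a warning.  >= 0.9 is the
    package's operational definition of "synchronized".
    """
    if traj.n_cells < 2:
        raise ValueError("synchrony needs at least 2 cells")
    w = traj.window(*window) if window else traj.window()
    x = {"c": w.c, "v": w.v, "s": w.s}[signal]
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~keep)} constant trace(s) from synchrony"
        )
    x = x[keep]
    if x.shape[0] < 2:
        return float("nan")
    corr = np.corrcoef(x)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


# ---------------------------------------------------------------------------
# Clamp-protocol helpers and export
# ---------------------------------------------------------------------------

def active_phase_windows(
    v: np.ndarray,
    dt: float,
    t0: float = 0.0,
    v_on: float = V_ON_DEFAULT,
    v_off: float = V_OFF_DEFAULT,
) -> list:
    """(start, end) times of detected supra-threshold (active) phases."""
    return [
        (e.t_start, e.t_end) for e in detect_events(v, dt, v_on=v_on, v_off=v_off, t0=t0)
    ]


def clamp_protocol_from_trace(
    traj: Trajectory,
    cell: int = 0,
    g_c: float = 0.05,
    v_fix: Optional[float] = None,
) -> ClampProtocol:
    """Build the clamped-partner protocol from a reference burster run.

    Windows are the burster's detected active phases over the full
    recorded trace; ``v_fix`` defaults to the mean voltage inside those
    windows (the plateau level).
    """
    v = traj.v[cell]
    dt = traj.dt
    t_start = float(traj.times[0])
    windows = active_phase_windows(v, dt, t0=t_start)
    if not windows:
        raise ValueError("reference trace contains no active phases")
    if v_fix is None:
        mask = np.zeros(v.size, dtype=bool)
        for w0, w1 in windows:
            i0 = int(round((w0 - t_start) / dt))
            i1 = int(round((w1 - t_start) / dt))
            mask[i0: i1 + 1] = True
        v_fix = float(v[mask].mean())
    return ClampProtocol(v_fix=v_fix, windows=tuple(windows), g_c=g_c)


def event_trains_to_frame(trains: Sequence[EventTrain]) -> pd.DataFrame:
    """Tidy table: cell, t_start, t_end, n_peaks, label."""
    rows = [
        {
            "cell": tr.cell,
            "t_start": e.t_start,
            "t_end": e.t_end,
            "n_peaks": e.n_peaks,
            "label": e.label,
        }
        for tr in trains
        for e in tr.events
    ]
    return pd.DataFrame(rows, columns=["cell", "t_start", "t_end", "n_peaks", "label"])


def event_trains_to_csv(trains: Sequence[EventTrain], path: Union[str, Path]) -> None:
    event_trains_to_frame(trains).to_csv(path, index=False)
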