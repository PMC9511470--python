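"""Oxygen-desaturation detection and the ODI / ODD reference metrics.

A desaturation is a maximal contiguous run of samples strictly below
(baseline - N) percentage points that lasts at least 10 s and at most
60 s; its timestamp is the first sub-threshold instant.  The baseline is
the mean of the first three minutes of the record and is held fixed.
ODI is the number of such events per hour of sleep (or per hour of
record when no sleep annotation is available); ODD at time t counts the
events timestamped in the trailing ten minutes (t - 600, t].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OximetryRecord, SleepAnnotation

__all__ = [
    "DesaturationEvent",
    "OddSeries",
    "compute_baseline",
    "detect_desaturations",
    "odi",
    "odd_series",
]


@dataclass
class DesaturationEvent:
    timestamp_s: float  # first instant below (baseline - N); equals start_s
    start_s: float
    end_s: float
    depth_pct: float  # baseline minus the run minimum
    duration_s: float


@dataclass
class OddSeries:
    times: np.ndarray
    counts: np.ndarray
    lookback_s: float = 600.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


def compute_baseline(record: OximetryRecord, minutes: float = 3.0) -> float:
    """Mean SaO2 over the first ``minutes`` of the record."""
    n = int(round(minutes * 60.0 * record.fs))
    if record.n < n:
        raise ValueError("record shorter than the baseline window")
    return float(record.values[:n].mean())


def detect_desaturations(
    record: OximetryRecord,
    baseline: float,
    n_pct: float = 3.0,
    min_dur_s: float = 10.0,
    max_dur_s: float = 60.0,
) -> list[DesaturationEvent]:
    """Maximal runs strictly below (baseline - n_pct), kept if 10-60 s long.

    Strict inequality implements "falls below": a sample exactly at the
    threshold terminates a run.  Durations are measured on the sample
    grid as run_length / fs, so at 0.1 Hz the 10-s minimum is a single
    sample — low-rate series give the detector very little to work with,
    which is precisely the weakness the recurrence biomarker avoids.
    """
    if n_pct <= 0:
        raise ValueError("n_pct must be positive")
    thresh = baseline - n_pct
    below = record.values < thresh
    z = np.concatenate(([0], below.view(np.int8), [0]))
    d = np.diff(z)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    events = []
    t0 = record.times[0]
    for a, b in zip(starts, ends):
        dur = (b - a) / record.fs
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        events.append(
            DesaturationEvent(
                timestamp_s=t0 + a / record.fs,
                start_s=t0 + a / record.fs,
                end_s=t0 + b / record.fs,
                depth_pct=float(baseline - record.values[a:b].min()),
                duration_s=dur,
            )
        )
    return events


def odi(
    events: list[DesaturationEvent],
    duration_s: float | None = None,
    sleep: SleepAnnotation | None = None,
) -> float:
    """Desaturations per hour of the reference period.

    With a sleep annotation, only events timestamped inside sleep
    intervals count and the divisor is total sleep time; otherwise the
    whole-record duration must be supplied.
    """
    if sleep is not None:
        ref_s = sleep.total_s
        count = sum(1 for e in events if sleep.contains(e.timestamp_s))
    else:
        if duration_s is None:
            raise ValueError("need duration_s or a sleep annotation")
        ref_s = float(duration_s)
        count = len(events)
    if ref_s <= 0:
        raise ValueError("reference duration must be positive")
    return count / (ref_s / 3600.0)


def odd_series(
    events: list[DesaturationEvent],
    t_grid: np.ndarray,
    lookback_s: float = 600.0,
) -> OddSeries:
    """Trailing-window event count: counts[t] = |{t - lookback < ts <= t}|."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing")
    ts = np.sort([e.timestamp_s for e in events])
    hi = np.searchsorted(ts, t_grid, side="right")
    lo = np.searchsorted(ts, t_grid - lookback_s, side="right")
    return OddSeries(times=t_grid, counts=hi - lo, lookback_s=lookback_s)
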