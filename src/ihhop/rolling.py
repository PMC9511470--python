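"""Rolling-window extraction of scalar metrics, eps_opt in particular.

A window of W seconds slides in steps of S seconds; a scalar metric f
turns each window into one value, so the record x becomes the series
{f(x[0:W]), f(x[S:S+W]), ..., f(x[N-W:N])}.  The final window is always
anchored to end exactly at the record end, even when N - W is not on the
step lattice (and is deduplicated when it is).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import OximetryRecord
from .recurrence import EpsOptEstimate, l_min_for_fs, segment_eps_opt

__all__ = ["EpsOptSeries", "window_start_indices", "rolling_apply", "rolling_eps_opt"]


@dataclass
class EpsOptSeries:
    """Per-window metric values (eps_opt unless stated otherwise)."""

    window_starts: np.ndarray  # seconds
    window_ends: np.ndarray  # seconds
    values: np.ndarray
    flags: np.ndarray  # True where the window was degenerate
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.window_ends = np.asarray(self.window_ends, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_windows(self) -> int:
        return int(self.values.size)


def window_start_indices(n: int, w: int, s: int) -> np.ndarray:
    """Start indices 0, s, 2s, ... plus an anchored final start at n - w."""
    if w > n:
        raise ValueError("window longer than record")
    if s < 1:
        raise ValueError("step must be at least one sample")
    starts = list(range(0, n - w + 1, s))
    if starts[-1] != n - w:
        starts.append(n - w)
    return np.asarray(starts, dtype=int)


def rolling_apply(
    record: OximetryRecord,
    window_s: float,
    step_s: float,
    metric: Callable[[np.ndarray], float | EpsOptEstimate],
) -> EpsOptSeries:
    """Apply ``metric`` to each [start, start + W) window of the record.

    The metric may return a plain float or an :class:`EpsOptEstimate`;
    in the latter case the degenerate flag is carried through.
    """
    w = int(round(window_s * record.fs))
    s = int(round(step_s * record.fs))
    starts = window_start_indices(record.n, w, s)
    values = np.empty(starts.size)
    flags = np.zeros(starts.size, dtype=bool)
    t0 = record.times[0]
    for i, a in enumerate(starts):
        out = metric(record.values[a : a + w])
        if isinstance(out, EpsOptEstimate):
            values[i] = out.value
            flags[i] = out.degenerate
        else:
            values[i] = float(out)
    return EpsOptSeries(
        window_starts=t0 + starts / record.fs,
        window_ends=t0 + (starts + w) / record.fs,
        values=values,
        flags=flags,
        window_s=window_s,
        step_s=step_s,
    )


def rolling_eps_opt(
    record: OximetryRecord,
    window_s: float = 300.0,
    step_s: float = 60.0,
    l_min: int | str = "auto",
    grid_points: int = 100,
) -> EpsOptSeries:
    """Rolling eps_opt series, the biomarker for intermittent oscillations.

    The defaults follow the segment geometry used for distribution and
    classification work (5-min windows, 1-min step); 10-min windows are
    the choice for comparison against the desaturation density.
    """
    lm = l_min_for_fs(record.fs) if l_min == "auto" else int(l_min)
    return rolling_apply(
        record,
        window_s,
        step_s,
        lambda x: segment_eps_opt(x, l_min=lm, fs=record.fs, grid_points=grid_points),
    )
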