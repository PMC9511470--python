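"""Reading and writing oximetry time series and sleep annotations.

The on-disk format is deliberately minimal: two-column delimited text
(time in seconds, SaO2 in percent), comma / tab / whitespace separated,
with an optional header row.  Sleep annotations are three-column CSV
(start_s, end_s, stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OximetryRecord",
    "SleepAnnotation",
    "read_oximetry",
    "write_oximetry",
    "read_sleep_annotation",
]

#: relative jitter allowed on the sampling grid before a file is rejected
GRID_JITTER_TOL = 0.01


@dataclass
class OximetryRecord:
    """A uniformly sampled arterial-oxygen-saturation (SaO2) series.

    Parameters
    ----------
    times : array of float
        Sample times in seconds from recording start, uniform grid.
    values : array of float
        SaO2 in percent.  Raw records may contain dropout sentinels
        (non-finite or non-positive values); after preprocessing all
        values lie in [0, 100].
    fs : float
        Sampling frequency in Hz (1.0 and 0.1 are the typical rates).
    valid_mask : array of bool, optional
        False where a sample was interpolated/filled rather than measured.
    """

    times: np.ndarray
    values: np.ndarray
    fs: float
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 1:
            raise ValueError("an oximetry record needs at least 1 sample")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > GRID_JITTER_TOL / self.fs:
                raise ValueError("times are not on a uniform 1/fs grid")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.size != self.values.size:
                raise ValueError("valid_mask length mismatch")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Record span in seconds, counting each sample as one 1/fs slot."""
        return self.n / self.fs

    @classmethod
    def from_values(
        cls,
        values: Sequence[float],
        fs: float,
        t0: float = 0.0,
        valid_mask: np.ndarray | None = None,
    ) -> "OximetryRecord":
        values = np.asarray(values, dtype=float)
        times = t0 + np.arange(values.size) / fs
        return cls(times=times, values=values, fs=fs, valid_mask=valid_mask)

    def replace_values(
        self, values: np.ndarray, valid_mask: np.ndarray | None = None
    ) -> "OximetryRecord":
        """New record on the same grid with different sample values."""
        mask = self.valid_mask if valid_mask is None else valid_mask
        return OximetryRecord(
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
            fs=self.fs,
            valid_mask=np.asarray(mask, dtype=bool).copy(),
        )


@dataclass
class SleepAnnotation:
    """Sleep intervals (start_s, end_s, stage) reported for a recording."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv[0])
        for start, end, _ in ivs:
            if not start < end:
                raise ValueError("sleep interval must have start < end")
        for (_, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("sleep intervals must not overlap")
        self.intervals = ivs

    @property
    def total_s(self) -> float:
        return float(sum(end - start for start, end, _ in self.intervals))

    def contains(self, t: float) -> bool:
        return any(start <= t < end for start, end, _ in self.intervals)


def _load_table(path: str | Path, n_cols: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=None, engine="python", header=None, comment="#",
            skip_blank_lines=True,
        )
    except Exception as exc:  # sniffing fails on empty/opaque input
        raise ValueError(f"{path}: cannot parse ({exc})") from exc
    if df.empty:
        raise ValueError(f"{path}: empty file")
    # drop an optional header row (non-numeric first field)
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().all():
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df.shape[1] < n_cols:
        raise ValueError(f"{path}: expected at least {n_cols} columns")
    return df


def read_oximetry(path: str | Path, fs_hint: float | None = None) -> OximetryRecord:
    """Read a two-column (time_s, sao2_pct) delimited text file.

    The sampling frequency is inferred from the median time step unless
    ``fs_hint`` is given.  Files whose time grid deviates from uniform by
    more than 1% jitter are rejected.
    """
    df = _load_table(path, 2)
    times = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(float)
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(times)):
        raise ValueError(f"{path}: non-numeric time values")
    if times.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: times not strictly increasing")
    step = float(np.median(dt)) if fs_hint is None else 1.0 / fs_hint
    if np.max(np.abs(dt - step)) > GRID_JITTER_TOL * step:
        raise ValueError(f"{path}: non-uniform sampling grid")
    fs = 1.0 / step
    # snap to an exact grid so downstream invariants hold to float precision
    times = times[0] + np.arange(times.size) * step
    return OximetryRecord(times=times, values=values, fs=fs)


def write_oximetry(record: OximetryRecord, path: str | Path) -> None:
    """Write a record back to the two-column CSV schema."""
    pd.DataFrame({"time_s": record.times, "sao2_pct": record.values}).to_csv(
        path, index=False
    )


def read_sleep_annotation(path: str | Path) -> SleepAnnotation:
    """Read a (start_s, end_s, stage) CSV; stage defaults to 'unspecified'."""
    df = _load_table(path, 2)
    intervals = []
    for _, row in df.iterrows():
        start = float(row.iloc[0])
        end = float(row.iloc[1])
        stage = str(row.iloc[2]).strip() if df.shape[1] > 2 else "unspecified"
        intervals.append((start, end, stage))
    return SleepAnnotation(intervals=intervals)
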