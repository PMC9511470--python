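"""Recurrence quantification for scalar time series.

The recurrence plot of a series x is the binary matrix

    R_ij = Theta(eps - |x_i - x_j|),

i.e. two time points are recurrent when their values lie within the
threshold eps of each other (no phase-space embedding: the comparison is
on the raw scalar samples).  Determinism,

    DET(eps; l_min) = sum_{l >= l_min} l P(l) / sum_{l >= 1} l P(l),

is the fraction of recurrent points that sit on diagonal lines of length
at least l_min, where P(l) is the histogram of maximal diagonal line
lengths outside a Theiler band around the main diagonal.  DET is close
to 1 for periodic signals and close to 0 for noise.

The optimal recurrence threshold

    eps_opt = argmax_eps  d DET(eps; l_min) / d eps

is the threshold at which DET rises fastest.  Ordered, quasi-constant
oximetry segments reach high DET at small eps (small eps_opt), while
segments carrying large intermittent sawtooth oscillations need a much
larger threshold (large eps_opt) — which is what makes eps_opt a usable
biomarker for those patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "RecurrenceMatrix",
    "DiagonalHistogram",
    "DetCurve",
    "EpsOptEstimate",
    "recurrence_matrix",
    "diagonal_histogram",
    "determinism",
    "default_eps_grid",
    "det_curve",
    "epsilon_opt",
    "segment_eps_opt",
    "l_min_for_fs",
]


def l_min_for_fs(fs: float, span_s: float = 10.0) -> int:
    """Minimal diagonal length spanning roughly ``span_s`` seconds.

    Gives 10 samples at 1 Hz and 2 samples at 0.1 Hz (the floor of 2
    keeps the line statistic meaningful at very low rates, where a
    single sample would make every recurrent point 'deterministic').
    """
    return max(2, int(round(span_s * fs)))


@dataclass
class RecurrenceMatrix:
    """Binary recurrence plot with its threshold and metric."""

    entries: np.ndarray
    epsilon: float
    metric: str = "absolute"

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=bool)
        n = self.entries.shape[0]
        if self.entries.ndim != 2 or self.entries.shape[1] != n:
            raise ValueError("recurrence matrix must be square")

    @property
    def n(self) -> int:
        return int(self.entries.shape[0])


@dataclass
class DiagonalHistogram:
    """Counts of maximal diagonal lines by exact length."""

    counts: dict[int, int]
    theiler: int = 1

    def total_points(self) -> int:
        """Sum over l of l * P(l): recurrent points on counted diagonals."""
        return int(sum(l * c for l, c in self.counts.items()))

    def points_at_least(self, l_min: int) -> int:
        return int(sum(l * c for l, c in self.counts.items() if l >= l_min))


@dataclass
class DetCurve:
    """DET evaluated on an increasing threshold grid for fixed l_min."""

    eps_grid: np.ndarray
    det_values: np.ndarray
    l_min: int
    empty_flags: np.ndarray  # True where the recurrence histogram was empty

    def __post_init__(self) -> None:
        self.eps_grid = np.asarray(self.eps_grid, dtype=float)
        self.det_values = np.asarray(self.det_values, dtype=float)
        self.empty_flags = np.asarray(self.empty_flags, dtype=bool)
        if not (self.eps_grid.size == self.det_values.size == self.empty_flags.size):
            raise ValueError("grid/values/flags length mismatch")
        if np.any(np.diff(self.eps_grid) <= 0):
            raise ValueError("eps grid must be strictly increasing")


class EpsOptEstimate(NamedTuple):
    value: float
    degenerate: bool


def recurrence_matrix(x: Sequence[float], epsilon: float) -> RecurrenceMatrix:
    """R_ij = 1 iff |x_i - x_j| <= epsilon (so the diagonal is all ones)."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D series with at least 2 samples")
    d = np.abs(x[:, None] - x[None, :])
    return RecurrenceMatrix(entries=d <= epsilon, epsilon=float(epsilon))


def _run_lengths(b: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    z = np.concatenate(([0], b.view(np.int8), [0]))
    d = np.diff(z)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def diagonal_histogram(R: RecurrenceMatrix, theiler: int = 1) -> DiagonalHistogram:
    """Histogram of maximal diagonal line lengths with offset |k| >= theiler.

    ``theiler=1`` (the default) excludes only the line of identity, which
    would otherwise contribute one artificial length-N line per plot.
    """
    n = R.n
    if not 0 <= theiler < n:
        raise ValueError("theiler must satisfy 0 <= theiler < N")
    counts: dict[int, int] = {}
    k0 = max(theiler, 1)
    for k in range(k0, n):
        lengths = _run_lengths(np.diagonal(R.entries, offset=k))
        for l in lengths:
            counts[int(l)] = counts.get(int(l), 0) + 2  # offsets +k and -k
    if theiler == 0:
        for l in _run_lengths(np.diagonal(R.entries)):
            counts[int(l)] = counts.get(int(l), 0) + 1
    return DiagonalHistogram(counts=counts, theiler=theiler)


def determinism(hist: DiagonalHistogram, l_min: int) -> float:
    """DET from a diagonal histogram; 0.0 if the histogram is empty."""
    if l_min < 1:
        raise ValueError("l_min must be >= 1")
    denom = hist.total_points()
    if denom == 0:
        return 0.0
    return hist.points_at_least(l_min) / denom


def default_eps_grid(
    x: Sequence[float], n_points: int = 100, min_spacing: float = 0.01
) -> np.ndarray:
    """Uniform threshold grid from 0 to the maximum pairwise distance.

    For narrow segments the grid is coarsened so that the spacing never
    drops below ``min_spacing`` signal units (a sub-noise-resolution grid
    would just sample measurement noise); the grid always has >= 3 points.
    """
    x = np.asarray(x, dtype=float)
    rng = float(np.max(x) - np.min(x))
    if rng <= min_spacing:
        return np.linspace(0.0, max(rng, min_spacing), 3)
    if rng / (n_points - 1) < min_spacing:
        n_points = max(3, int(rng / min_spacing) + 1)
    return np.linspace(0.0, rng, n_points)


def _diagonal_profiles(x: np.ndarray, theiler: int, l_min: int):
    """Flattened per-diagonal distance profile and its line-structure floor.

    Returns (d, c, d0, c0) where d concatenates |x_{i+k} - x_i| over all
    upper offsets k >= max(theiler, 1) (weight 2 by symmetry), d0 is the
    k = 0 diagonal (weight 1, only used when theiler == 0), and c / c0
    give, for each cell, the smallest eps at which that cell belongs to a
    fully recurrent run of length >= l_min: the minimum over all windows
    of l_min consecutive cells containing it of the window maximum
    (a sliding max followed by a sliding min, with +inf separators so
    runs never bridge distinct diagonals).
    """
    n = x.size
    k0 = max(theiler, 1)
    pieces = [np.abs(x[k:] - x[:-k]) for k in range(k0, n)]
    sep = np.full(l_min, np.inf)
    flat_parts: list[np.ndarray] = []
    for p in pieces:
        flat_parts.append(p)
        flat_parts.append(sep)
    flat = np.concatenate(flat_parts) if flat_parts else np.array([])

    def closing(f: np.ndarray) -> np.ndarray:
        if f.size < l_min:
            return np.full(f.size, np.inf)
        from numpy.lib.stride_tricks import sliding_window_view

        m = sliding_window_view(f, l_min).max(axis=-1)
        pad = np.full(l_min - 1, np.inf)
        m2 = np.concatenate([pad, m, pad])
        return sliding_window_view(m2, l_min).min(axis=-1)[: f.size]

    c = closing(flat)
    valid = np.isfinite(flat)
    d = flat[valid]
    cv = c[valid] if c.size else c
    if theiler == 0:
        d0 = np.zeros(n)  # the identity diagonal has distance 0 everywhere
        c0 = np.zeros(n) if n >= l_min else np.full(n, np.inf)
    else:
        d0 = np.array([])
        c0 = np.array([])
    return d, cv, d0, c0


def det_curve(
    x: Sequence[float],
    eps_grid: np.ndarray | None = None,
    l_min: int = 10,
    theiler: int = 1,
) -> DetCurve:
    """DET(eps; l_min) on a threshold grid.

    Equivalent to composing ``recurrence_matrix`` -> ``diagonal_histogram``
    -> ``determinism`` at every grid point, but computed from sorted
    per-diagonal distance profiles so the full curve costs two sorts and a
    pair of binary searches per threshold.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D series with at least 2 samples")
    if eps_grid is None:
        eps_grid = default_eps_grid(x)
    eps_grid = np.asarray(eps_grid, dtype=float)
    if eps_grid.size < 3:
        raise ValueError("eps grid needs at least 3 points")
    if np.any(np.diff(eps_grid) <= 0):
        raise ValueError("eps grid must be strictly increasing")
    if l_min < 1:
        raise ValueError("l_min must be >= 1")

    d, c, d0, c0 = _diagonal_profiles(x, theiler, l_min)
    ds, cs = np.sort(d), np.sort(c)
    denom = 2.0 * np.searchsorted(ds, eps_grid, side="right")
    numer = 2.0 * np.searchsorted(cs, eps_grid, side="right")
    if d0.size:
        denom += np.searchsorted(np.sort(d0), eps_grid, side="right")
        numer += np.searchsorted(np.sort(c0), eps_grid, side="right")
    empty = denom == 0
    det = np.zeros_like(denom)
    np.divide(numer, denom, out=det, where=~empty)
    return DetCurve(eps_grid=eps_grid, det_values=det, l_min=l_min, empty_flags=empty)


def epsilon_opt(curve: DetCurve) -> EpsOptEstimate:
    """Grid threshold maximising the finite-difference slope of DET(eps).

    Central differences in the interior, one-sided at the grid ends; ties
    resolve to the smallest eps.  A flat curve (constant DET, e.g. a
    constant segment) or an everywhere-empty histogram is reported as
    degenerate with the smallest grid value.
    """
    det = curve.det_values
    eps = curve.eps_grid
    if bool(curve.empty_flags.all()) or float(np.ptp(det)) < 1e-12:
        return EpsOptEstimate(value=float(eps[0]), degenerate=True)
    deriv = np.gradient(det, eps)
    i = int(np.argmax(deriv))  # argmax returns the first (smallest-eps) maximum
    return EpsOptEstimate(value=float(eps[i]), degenerate=False)


def segment_eps_opt(
    x: Sequence[float],
    l_min: int | str = "auto",
    fs: float = 1.0,
    grid_points: int = 100,
    theiler: int = 1,
) -> EpsOptEstimate:
    """eps_opt of a single segment, with l_min resolved from fs if 'auto'."""
    if l_min == "auto":
        l_min = l_min_for_fs(fs)
    grid = default_eps_grid(np.asarray(x, dtype=float), n_points=grid_points)
    curve = det_curve(x, eps_grid=grid, l_min=int(l_min), theiler=theiler)
    return epsilon_opt(curve)
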