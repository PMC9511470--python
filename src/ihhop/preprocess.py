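"""Preprocessing chain for oximetry series.

Three steps, in the order clip -> filter -> resample:

1. ``clip_and_interpolate`` — SaO2 readings below a physiological floor
   (default 75%) are treated as dropouts and linearly interpolated from
   the nearest valid neighbours.
2. ``lowpass_filter`` — zero-phase low-pass (default cutoff 0.25 Hz)
   removing measurement noise faster than any physiological desaturation.
3. ``resample_block_average`` — optional decimation by non-overlapping
   block averaging (default 10 s blocks, i.e. 1 Hz -> 0.1 Hz).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .io import OximetryRecord

__all__ = [
    "clip_and_interpolate",
    "lowpass_filter",
    "resample_block_average",
    "preprocess",
]


def clip_and_interpolate(record: OximetryRecord, floor: float = 75.0) -> OximetryRecord:
    """Replace sub-floor / dropout samples by linear interpolation.

    Samples that are non-finite, non-positive, or strictly below ``floor``
    are marked invalid and filled by linear interpolation between the
    nearest valid neighbours; invalid runs touching the record boundary
    are filled by nearest-valid constant extension.  Raises if no sample
    is valid.
    """
    v = record.values
    invalid = ~np.isfinite(v) | (v <= 0.0) | (v < floor)
    if invalid.all():
        raise ValueError("unusable record: every sample is below the floor")
    if not invalid.any():
        return record.replace_values(v.copy(), record.valid_mask & ~invalid)
    idx = np.arange(v.size)
    good = idx[~invalid]
    # np.interp holds the boundary values constant outside [good[0], good[-1]]
    filled = v.copy()
    filled[invalid] = np.interp(idx[invalid], good, v[good])
    return record.replace_values(filled, record.valid_mask & ~invalid)


def lowpass_filter(
    record: OximetryRecord, cutoff: float = 0.25, order: int = 4
) -> OximetryRecord:
    """Zero-phase Butterworth low-pass filter (forward-backward).

    DC gain is 1, so the saturation level is preserved; the zero-phase
    application keeps desaturation onsets where they are, which matters
    for event timestamps downstream.
    """
    nyq = record.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {nyq})")
    sos = signal.butter(order, cutoff, btype="low", fs=record.fs, output="sos")
    padlen = min(3 * (2 * order + 1), record.n - 1)
    filtered = signal.sosfiltfilt(sos, record.values, padlen=padlen)
    return record.replace_values(filtered)


def resample_block_average(record: OximetryRecord, block_s: float = 10.0) -> OximetryRecord:
    """Decimate by averaging non-overlapping blocks of ``block_s`` seconds.

    The trailing partial block, if any, is dropped.  Output sampling
    frequency is 1/block_s; output times are the block start times.
    A block is marked valid only if every sample in it was valid.
    """
    m_f = block_s * record.fs
    m = int(round(m_f))
    if m < 1 or abs(m_f - m) > 1e-6:
        raise ValueError("block_s must be an integer multiple of 1/fs")
    n_blocks = record.n // m
    if n_blocks < 1:
        raise ValueError("record shorter than one block")
    v = record.values[: n_blocks * m].reshape(n_blocks, m)
    mask = record.valid_mask[: n_blocks * m].reshape(n_blocks, m)
    times = record.times[0] + np.arange(n_blocks) * block_s
    return OximetryRecord(
        times=times,
        values=v.mean(axis=1),
        fs=1.0 / block_s,
        valid_mask=mask.all(axis=1),
    )


def preprocess(
    record: OximetryRecord,
    floor: float = 75.0,
    cutoff: float = 0.25,
    resample_s: float | None = None,
) -> OximetryRecord:
    """Full chain: clip/interpolate, zero-phase low-pass, optional resample."""
    out = clip_and_interpolate(record, floor=floor)
    if cutoff is not None:
        out = lowpass_filter(out, cutoff=cutoff)
    if resample_s is not None:
        out = resample_block_average(out, block_s=resample_s)
    return out
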