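import numpy as np
import pytest

from ihhop import OximetryRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(values, fs=1.0):
    return OximetryRecord.from_values(np.asarray(values, dtype=float), fs=fs)


def brute_diagonal_histogram(R: np.ndarray, theiler: int = 1) -> dict[int, int]:
    """Independent oracle: walk every diagonal cell by cell, counting
    maximal runs of ones on all diagonals with offset |k| >= theiler."""
    n = R.shape[0]
    counts: dict[int, int] = {}
    for k in range(-(n - 1), n):
        if abs(k) < theiler:
            continue
        run = 0
        for i in range(n):
            j = i + k
            if 0 <= j < n and R[i, j]:
                run += 1
            else:
                if run:
                    counts[run] = counts.get(run, 0) + 1
                run = 0
        if run:
            counts[run] = counts.get(run, 0) + 1
    return counts


def brute_det(R: np.ndarray, l_min: int, theiler: int = 1) -> float:
    counts = brute_diagonal_histogram(R, theiler)
    denom = sum(l * c for l, c in counts.items())
    if denom == 0:
        return 0.0
    return sum(l * c for l, c in counts.items() if l >= l_min) / denom
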