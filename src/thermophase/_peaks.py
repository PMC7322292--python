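"""Plateau-aware interior local-maximum detection.

A sample is a local maximum when it is strictly greater than the nearest
distinct values on both sides; a flat plateau counts once, at its first
index.  Endpoints never qualify, and plateaus touching an endpoint are
discarded because the outer neighbour is unknown.
"""

from __future__ import annotations

import numpy as np


def local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima of ``y`` (plateau -> first index)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    idx: list[int] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j + 1 < n and y[j + 1] < y[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as inclusive (start, stop) index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))
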