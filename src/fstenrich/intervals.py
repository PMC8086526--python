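"""Exact interval algebra on 0-based half-open genomic intervals.

Every function operates on a single chromosome's intervals, represented as an
``(N, 2)`` int64 array of ``[start, end)`` rows.  Inputs to :func:`merge` may
be unsorted and overlapping; all other functions require *merged* input (sorted,
non-overlapping, non-abutting), which is what :func:`merge` produces.  Standard
set semantics throughout; abutting intervals are coalesced.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_interval_array",
    "merge",
    "intersect",
    "subtract",
    "complement",
    "total_length",
    "contains_points",
]

_EMPTY = np.empty((0, 2), dtype=np.int64)


def as_interval_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an (N, 2) int64 array."""
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return _EMPTY.copy()
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (N, 2) interval array, got shape {arr.shape}")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("malformed interval: start must be < end")
    if np.any(arr[:, 0] < 0):
        raise ValueError("malformed interval: negative start")
    return arr


def merge(intervals, merge_abutting: bool = True) -> np.ndarray:
    """Sort and merge intervals into a canonical disjoint set."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    cummax_end = np.maximum.accumulate(arr[:, 1])
    if merge_abutting:
        new_block = arr[1:, 0] > cummax_end[:-1]
    else:
        new_block = arr[1:, 0] >= cummax_end[:-1]
    block = np.concatenate(([0], np.cumsum(new_block)))
    n_blocks = block[-1] + 1
    starts = np.zeros(n_blocks, dtype=np.int64)
    ends = np.zeros(n_blocks, dtype=np.int64)
    first = np.concatenate(([True], new_block))
    starts = arr[first, 0]
    np.maximum.at(ends, block, arr[:, 1])
    return np.column_stack([starts, ends])


def complement(merged: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Gaps of a merged interval set within [lo, hi)."""
    merged = np.asarray(merged, dtype=np.int64)
    if lo >= hi:
        return _EMPTY.copy()
    if len(merged) == 0:
        return np.array([[lo, hi]], dtype=np.int64)
    # clip the set to the window first
    starts = np.clip(merged[:, 0], lo, hi)
    ends = np.clip(merged[:, 1], lo, hi)
    keep = starts < ends
    starts, ends = starts[keep], ends[keep]
    gap_starts = np.concatenate(([lo], ends))
    gap_ends = np.concatenate((starts, [hi]))
    keep = gap_starts < gap_ends
    return np.column_stack([gap_starts[keep], gap_ends[keep]])


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set intersection of two merged interval sets."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        return _EMPTY.copy()
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return _EMPTY.copy()
    return np.array(out, dtype=np.int64)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b of two merged interval sets."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if len(a) == 0:
        return _EMPTY.copy()
    if len(b) == 0:
        return a.copy()
    lo = min(a[0, 0], b[0, 0])
    hi = max(a[-1, 1], b[-1, 1])
    return intersect(a, complement(b, lo, hi))


def total_length(intervals: np.ndarray) -> int:
    """Total bases covered by a merged interval set."""
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return 0
    return int(np.sum(arr[:, 1] - arr[:, 0]))


def contains_points(merged: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Boolean membership of 0-based positions in a merged interval set.

    A position belongs to interval [start, end) iff start <= pos < end.
    """
    pos = np.asarray(pos, dtype=np.int64)
    merged = np.asarray(merged, dtype=np.int64)
    if len(merged) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    inside = idx >= 0
    inside[inside] = pos[inside] < merged[idx[inside], 1]
    return inside
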