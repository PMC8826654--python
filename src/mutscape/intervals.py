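"""Interval arithmetic on 0-based half-open intervals.

All functions accept an ``(n, 2)`` integer array (or an iterable of
``(start, end)`` pairs) and return merged, sorted ``(n, 2)`` arrays.
Empty interval sets are represented by a ``(0, 2)`` array.
"""

from __future__ import annotations

import numpy as np

EMPTY = np.empty((0, 2), dtype=np.int64)


def as_array(intervals) -> np.ndarray:
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals, dtype=np.int64)
    if arr.size == 0:
        return EMPTY.copy()
    return arr.reshape(-1, 2)


def merge(intervals) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_length(intervals) -> int:
    arr = merge(intervals)
    return int((arr[:, 1] - arr[:, 0]).sum()) if len(arr) else 0


def complement(intervals, length: int) -> np.ndarray:
    """Complement within [0, length)."""
    arr = merge(intervals)
    out = []
    prev = 0
    for s, e in arr:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return as_array(out)


def subtract(a, b, length: int | None = None) -> np.ndarray:
    """Set difference a \\ b."""
    a = merge(a)
    if len(a) == 0:
        return a
    hi = int(a[:, 1].max()) if length is None else length
    return intersect(a, complement(b, hi))


def intersect(a, b) -> np.ndarray:
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_array(out)


def contains_points(intervals, positions) -> np.ndarray:
    """Boolean membership for 0-based positions (vectorised)."""
    arr = merge(intervals)
    pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    if len(arr) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < arr[idx[ok], 1]
    return ok
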