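"""Interval-set arithmetic shared across modules.

All functions operate on 0-based half-open intervals grouped per chromosome
as (start, end) numpy arrays, or directly on lists of GenomicInterval.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .model import GenomicInterval

__all__ = [
    "by_chrom",
    "merge",
    "union_bp",
    "intersect_bp",
    "point_in_any",
    "nearest_gap",
]


def by_chrom(intervals) -> dict[str, np.ndarray]:
    """Group intervals into per-chromosome sorted (n, 2) start/end arrays."""
    d: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        d[iv.chrom].append((iv.start, iv.end))
    return {
        c: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        for c, pairs in d.items()
    }


def merge(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent sorted intervals into a disjoint set."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def union_bp(intervals) -> int:
    """Total bases covered by the union of intervals."""
    total = 0
    for arr in by_chrom(intervals).values():
        m = merge(arr)
        total += int((m[:, 1] - m[:, 0]).sum())
    return total


def intersect_bp(a_ivs, b_ivs) -> int:
    """Bases in the intersection of two interval sets."""
    a_by, b_by = by_chrom(a_ivs), by_chrom(b_ivs)
    total = 0
    for c in set(a_by) & set(b_by):
        a, b = merge(a_by[c]), merge(b_by[c])
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
    return total


def point_in_any(chrom: str, pos: int, merged: dict[str, np.ndarray]) -> bool:
    """Membership test of a point against per-chromosome MERGED intervals."""
    arr = merged.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
    return i >= 0 and pos < arr[i, 1]


def nearest_gap(chrom: str, pos: int, merged: dict[str, np.ndarray]) -> int | None:
    """Distance from a point to the closest interval boundary, 0 if inside.

    Returns None when the chromosome holds no intervals.
    """
    arr = merged.get(chrom)
    if arr is None or len(arr) == 0:
        return None
    if point_in_any(chrom, pos, merged):
        return 0
    starts, ends = arr[:, 0], arr[:, 1]
    i = int(np.searchsorted(starts, pos, side="right"))
    cands = []
    if i > 0:
        cands.append(pos - ends[i - 1])
    if i < len(arr):
        cands.append(starts[i] - pos)
    return int(min(cands))


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """End-to-start gap between two intervals; 0 when they overlap or touch."""
    if a.chrom != b.chrom:
        raise ValueError("intervals on different chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))
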