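"""Threshold segmentation of standardized genomic signal.

The biological cutoff (bc) is interpreted as a z-score threshold on the
genome-standardized track: positive segments are maximal runs of windows
with z >= bc (hypersensitive), negative segments runs with z <= -bc
(MNase-resistant). bc 0.5 is lenient, bc 2.0 the default working
stringency for hypersensitive regions, bc 4.0 for footprints. Replicates
are reconciled by greedy nearest-midpoint matching within 300 bp.
"""

from __future__ import annotations

import numpy as np

from . import intervals as ivt
from .model import GenomeModel, GenomicInterval, Segment, SegmentSet, WindowedSignal

__all__ = [
    "standardize",
    "call_segments",
    "high_confidence",
    "set_comparison",
    "accessible_fraction",
]


def standardize(signal: WindowedSignal, robust: bool = False) -> WindowedSignal:
    """Z-scale a track using moments over every window of the genome.

    With ``robust=True``, centre by the median and scale by 1.4826*MAD
    instead of mean/SD.
    """
    allv = signal.concat()
    if robust:
        center = np.median(allv)
        scale = 1.4826 * np.median(np.abs(allv - center))
    else:
        center = allv.mean()
        scale = allv.std(ddof=0)
    if scale == 0:
        raise ValueError("signal has zero variance; cannot standardize")
    return signal.copy_with({c: (v - center) / scale for c, v in signal.values.items()})


def _runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True, merging runs separated by <= max_gap False windows."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((int(start), int(prev) + 1))
            start = prev = i
    runs.append((int(start), int(prev) + 1))
    return runs


def call_segments(z: WindowedSignal, bc: float, max_gap_windows: int = 0,
                  sign: str = "both", source: str = "") -> SegmentSet:
    """Call segments where |z| exceeds the biological cutoff.

    Positive segments are maximal runs of windows with z >= bc (runs
    separated by at most ``max_gap_windows`` sub-threshold windows are
    merged); negative segments use z <= -bc. The score is the mean z over
    all member windows, gap windows included.
    """
    if bc <= 0:
        raise ValueError("bc must be positive")
    if sign not in ("+", "-", "both"):
        raise ValueError(f"bad sign {sign!r}")
    width = z.width
    segs: list[Segment] = []
    for chrom, length in z.genome.chromosomes:
        v = z.values[chrom]
        for sgn, mask in (("+", v >= bc), ("-", v <= -bc)):
            if sign != "both" and sgn != sign:
                continue
            for i0, i1 in _runs(mask, max_gap_windows):
                iv = GenomicInterval(chrom, i0 * width, min(i1 * width, length), ".")
                segs.append(Segment(iv, sgn, float(v[i0:i1].mean())))
    segs.sort(key=lambda s: (z.genome.names.index(s.interval.chrom), s.interval.start))
    return SegmentSet(segs, source)


def high_confidence(set_a: SegmentSet, set_b: SegmentSet,
                    max_mid_dist: int = 300) -> SegmentSet:
    """Reconcile two replicate segment sets.

    Retains pairs of equal-sign segments whose midpoints lie within
    ``max_mid_dist`` bp, pairing greedily by nearest midpoint with each
    segment used at most once; the emitted interval is the union span of
    the pair and the score the mean of the two scores.
    """
    pairs = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if a.sign != b.sign or a.interval.chrom != b.interval.chrom:
                continue
            d = abs(a.midpoint - b.midpoint)
            if d <= max_mid_dist:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = set_a.segments[i], set_b.segments[j]
        iv = GenomicInterval(
            a.interval.chrom,
            min(a.interval.start, b.interval.start),
            max(a.interval.end, b.interval.end),
            ".",
        )
        out.append(Segment(iv, a.sign, (a.score + b.score) / 2))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return SegmentSet(out, f"high_confidence({set_a.source},{set_b.source})")


def set_comparison(set_a, set_b) -> dict[str, float]:
    """Base-pair accounting of two region sets (shared/exclusive/Jaccard)."""
    ivs_a = set_a.intervals() if isinstance(set_a, SegmentSet) else list(set_a)
    ivs_b = set_b.intervals() if isinstance(set_b, SegmentSet) else list(set_b)
    a_bp = ivt.union_bp(ivs_a)
    b_bp = ivt.union_bp(ivs_b)
    shared = ivt.intersect_bp(ivs_a, ivs_b)
    union = a_bp + b_bp - shared
    return {
        "shared_bp": shared,
        "onlyA_bp": a_bp - shared,
        "onlyB_bp": b_bp - shared,
        "jaccard": shared / union if union else 0.0,
    }


def accessible_fraction(segments, genome: GenomeModel) -> float:
    """Percent of the genome covered by the union of the segments."""
    ivs = segments.intervals() if isinstance(segments, SegmentSet) else list(segments)
    return 100.0 * ivt.union_bp(ivs) / genome.total_bp
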