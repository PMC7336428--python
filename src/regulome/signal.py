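"""Windowed accessibility tracks from paired MNase digests.

The differential nuclease sensitivity (DNS) track is the light-digest minus
heavy-digest normalized coverage; positive values mark accessible chromatin,
negative values MNase-resistant (nucleosome-occupied) chromatin. The LCS
track is the light-digest coverage restricted to sub-nucleosomal (<131 bp)
fragments, a proxy for TF-scale particles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import FragmentSet, GenomeModel, WindowedSignal

__all__ = [
    "size_partition",
    "window_coverage",
    "rpm_scale",
    "dns_track",
    "lcs_track",
    "replicate_correlation",
    "genome_summary",
]

SMALL_FRAGMENT_CUTOFF = 131  # bp; fragments strictly below are sub-nucleosomal


def size_partition(frags: FragmentSet, cutoff: int = SMALL_FRAGMENT_CUTOFF):
    """Split fragments into (small, large) by length, small = length < cutoff."""
    small = [iv for iv in frags.intervals if len(iv) < cutoff]
    large = [iv for iv in frags.intervals if len(iv) >= cutoff]
    return (
        FragmentSet(small, frags.digest, frags.replicate),
        FragmentSet(large, frags.digest, frags.replicate),
    )


def window_coverage(frags: FragmentSet, genome: GenomeModel, width: int = 25) -> WindowedSignal:
    """Mean per-base fragment depth in fixed windows.

    The depth of base b is the number of fragments whose interval contains b;
    a window's value is the mean depth over its bases, with the final partial
    window averaged over its true width.
    """
    diffs = {name: np.zeros(length + 1) for name, length in genome.chromosomes}
    for iv in frags.intervals:
        if iv.chrom not in diffs:
            raise ValueError(f"fragment on unknown chromosome {iv.chrom!r}")
        if iv.end > genome.length(iv.chrom):
            raise ValueError(
                f"fragment {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
            )
        diffs[iv.chrom][iv.start] += 1
        diffs[iv.chrom][iv.end] -= 1

    values = {}
    for name, length in genome.chromosomes:
        depth = np.cumsum(diffs[name][:-1])
        n = -(-length // width)
        starts = np.arange(n) * width
        sums = np.add.reduceat(depth, starts)
        widths = np.minimum(starts + width, length) - starts
        values[name] = sums / widths
    return WindowedSignal(genome, width, values)


def rpm_scale(signal: WindowedSignal, total_fragments: int) -> WindowedSignal:
    """Scale to reads-per-million of the parent library.

    ``total_fragments`` is the library size of the originating fragment set
    (before any size filtering), so size-class tracks share a scale with
    all-fragment tracks.
    """
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    f = 1e6 / total_fragments
    return signal.copy_with({c: v * f for c, v in signal.values.items()})


def dns_track(light_rpm: WindowedSignal, heavy_rpm: WindowedSignal) -> WindowedSignal:
    """Differential nuclease sensitivity: light minus heavy, per window."""
    if not light_rpm.compatible(heavy_rpm):
        raise ValueError("light and heavy tracks have mismatched genome or width")
    return light_rpm.copy_with(
        {c: light_rpm.values[c] - heavy_rpm.values[c] for c in light_rpm.values}
    )


def lcs_track(light: FragmentSet, genome: GenomeModel, width: int = 25,
              cutoff: int = SMALL_FRAGMENT_CUTOFF) -> WindowedSignal:
    """Light-digest coverage of small (<cutoff bp) fragments, RPM-scaled.

    The RPM denominator is the full light library, not the small subset.
    """
    if light.digest != "light":
        raise ValueError("LCS is defined on the light digest")
    small, _ = size_partition(light, cutoff)
    return rpm_scale(window_coverage(small, genome, width), len(light))


def replicate_correlation(sig_a: WindowedSignal, sig_b: WindowedSignal) -> float:
    """Pearson correlation of two tracks over all windows."""
    if not sig_a.compatible(sig_b):
        raise ValueError("tracks have mismatched genome or width")
    r, _ = stats.pearsonr(sig_a.concat(), sig_b.concat())
    return float(r)


def genome_summary(signal: WindowedSignal, win: int = 1_000_000,
                   step: int = 100_000, stat: str = "mean") -> pd.DataFrame:
    """Sliding large-window summaries of a fine-grained track.

    One row per (chromosome, window start); window starts are multiples of
    ``step``. ``stat`` is 'mean' (mean of member window values) or
    'positive_z' (mean of the positive member values, 0 when none positive).
    """
    if stat not in ("mean", "positive_z"):
        raise ValueError(f"unknown stat {stat!r}")
    rows = []
    width = signal.width
    for chrom, length in signal.genome.chromosomes:
        v = signal.values[chrom]
        starts = [0] if length < win else range(0, length - win + 1, step)
        for s in starts:
            e = min(s + win, length)
            members = v[s // width: -(-e // width)]
            if stat == "mean":
                val = float(members.mean())
            else:
                pos = members[members > 0]
                val = float(pos.mean()) if len(pos) else 0.0
            rows.append({"chrom": chrom, "start": s, "end": e, "value": val})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
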