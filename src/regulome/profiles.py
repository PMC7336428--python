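"""Composite metaplots around genes and transcripts.

Window-valued signals are sampled at base resolution (each base takes its
window's value), aligned strand-aware, and averaged across regions.
Profiles report means, not sums, so groups of different sizes stay
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import WindowedSignal

__all__ = [
    "CompositeProfile",
    "expression_tertiles",
    "tss_metaplot",
    "metagene_profile",
    "methylation_profile",
]


@dataclass
class CompositeProfile:
    """Mean signal per offset with per-offset contributor counts."""

    x: np.ndarray           # offsets (bp) or scaled-bin labels
    y: np.ndarray           # mean signal; NaN where no contributors
    n: np.ndarray           # contributing regions per offset

    def __post_init__(self):
        if not (len(self.x) == len(self.y) == len(self.n)):
            raise ValueError("profile arrays must share a length")


def expression_tertiles(tpm: dict[str, float]) -> tuple[list[str], list[str], list[str]]:
    """Split genes into (low, mid, high) expression tertiles.

    Genes are sorted by TPM (ties broken by id); group sizes differ by at
    most one, with remainders going to the lowest groups first.
    """
    order = sorted(tpm, key=lambda g: (tpm[g], g))
    m = len(order)
    base, rem = divmod(m, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    low = order[: sizes[0]]
    mid = order[sizes[0]: sizes[0] + sizes[1]]
    high = order[sizes[0] + sizes[1]:]
    return low, mid, high


def _base_values(signal: WindowedSignal, chrom: str) -> np.ndarray:
    length = signal.genome.length(chrom)
    return np.repeat(signal.values[chrom], signal.width)[:length]


def tss_metaplot(signal: WindowedSignal, genes, flank: int = 1000) -> CompositeProfile:
    """Mean signal at offsets -flank..+flank around gene TSSs, strand-aware.

    Minus-strand genes are flipped so positive offsets always point into the
    gene body. Genes whose window runs off the chromosome contribute only
    their in-bounds offsets.
    """
    offsets = np.arange(-flank, flank + 1)
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=int)
    base_cache: dict[str, np.ndarray] = {}
    for g in genes:
        chrom = g.interval.chrom
        if chrom not in base_cache:
            base_cache[chrom] = _base_values(signal, chrom)
        bv = base_cache[chrom]
        tss = g.tss
        if g.strand != "-":
            pos = tss + offsets
        else:
            pos = tss - offsets
        ok = (pos >= 0) & (pos < len(bv))
        total[ok] += bv[pos[ok]]
        count[ok] += 1
    y = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return CompositeProfile(offsets, y, count)


def _scaled_body(values: np.ndarray, body_bins: int) -> np.ndarray:
    """Average base-level values into ``body_bins`` near-equal bins."""
    edges = np.linspace(0, len(values), body_bins + 1)
    out = np.empty(body_bins)
    for i in range(body_bins):
        lo, hi = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
        out[i] = values[lo:hi].mean()
    return out


def metagene_profile(signal: WindowedSignal, transcripts, body_bins: int = 100,
                     flank: int = 1000) -> CompositeProfile:
    """Scaled metagene: fixed-bp flanks around a body rescaled to ``body_bins``.

    x is -flank..-1 (upstream, bp), then body bin indices 0..body_bins-1,
    then 1..flank (downstream, bp). Strand-aware.
    """
    n_pts = 2 * flank + body_bins
    total = np.zeros(n_pts)
    count = np.zeros(n_pts, dtype=int)
    base_cache: dict[str, np.ndarray] = {}
    for t in transcripts:
        iv = t.interval if hasattr(t, "interval") else t
        chrom = iv.chrom
        if chrom not in base_cache:
            base_cache[chrom] = _base_values(signal, chrom)
        bv = base_cache[chrom]
        body = bv[iv.start: iv.end]
        up = np.full(flank, np.nan)
        lo = max(0, iv.start - flank)
        if iv.start - lo:
            up[flank - (iv.start - lo):] = bv[lo: iv.start]
        down = np.full(flank, np.nan)
        hi = min(len(bv), iv.end + flank)
        if hi - iv.end:
            down[: hi - iv.end] = bv[iv.end: hi]
        row = np.concatenate([up, _scaled_body(body, body_bins), down])
        if iv.strand == "-":
            row = row[::-1]
        ok = ~np.isnan(row)
        total[ok] += row[ok]
        count[ok] += 1
    x = np.concatenate([np.arange(-flank, 0), np.arange(body_bins), np.arange(1, flank + 1)])
    y = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return CompositeProfile(x, y, count)


def methylation_profile(methylation: pd.DataFrame, transcripts, context: str,
                        body_bins: int = 100, flank: int = 1000,
                        flank_bins: int = 50) -> CompositeProfile:
    """Mean per-cytosine methylation ratio across a composite transcript model.

    ``methylation`` has columns (chrom, position, context, ratio). Flanks and
    the scaled body are divided into bins; each bin's value is the mean ratio
    of the cytosines of the requested context falling in it, averaged over
    transcripts. Bins containing no cytosine are missing (NaN), not zero.
    """
    if context not in ("CG", "CHG", "CHH"):
        raise ValueError(f"unknown context {context!r}")
    sub = methylation[methylation["context"] == context]
    by_chrom = {c: g.sort_values("position") for c, g in sub.groupby("chrom")}
    n_pts = 2 * flank_bins + body_bins
    total = np.zeros(n_pts)
    count = np.zeros(n_pts, dtype=int)
    for t in transcripts:
        iv = t.interval if hasattr(t, "interval") else t
        g = by_chrom.get(iv.chrom)
        if g is None:
            continue
        pos = g["position"].to_numpy()
        ratio = g["ratio"].to_numpy()
        row = np.full(n_pts, np.nan)
        # upstream flank bins (genomic left of start for '+')
        up_edges = np.linspace(iv.start - flank, iv.start, flank_bins + 1)
        body_edges = np.linspace(iv.start, iv.end, body_bins + 1)
        down_edges = np.linspace(iv.end, iv.end + flank, flank_bins + 1)
        edges = np.concatenate([up_edges[:-1], body_edges[:-1], down_edges])
        for i in range(n_pts):
            lo, hi = edges[i], edges[i + 1]
            sel = (pos >= lo) & (pos < hi)
            if sel.any():
                row[i] = ratio[sel].mean()
        if iv.strand == "-":
            row = row[::-1]
        ok = ~np.isnan(row)
        total[ok] += row[ok]
        count[ok] += 1
    x = np.concatenate([
        np.arange(-flank_bins, 0), np.arange(body_bins), np.arange(1, flank_bins + 1)
    ])
    y = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return CompositeProfile(x, y, count)
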