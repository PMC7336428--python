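"""Genomic context of called regions.

Feature assignment and density, distance-to-gene statistics, circular
permutation enrichment, ChIP-peak concordance and co-binding, motif
proximity modules, and hypergeometric term enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as ivt
from .model import AnnotationSet, GenomeModel, GenomicInterval, Segment, SegmentSet

__all__ = [
    "FEATURE_LABELS",
    "feature_spaces",
    "assign_feature",
    "feature_density",
    "nearest_gene_distance",
    "gap_null",
    "distance_test",
    "EnrichmentResult",
    "permutation_enrichment",
    "chip_concordance",
    "cobound",
    "overlap_with",
    "motif_proximity",
    "term_enrichment",
]

# exclusive-assignment precedence, highest first
FEATURE_LABELS = [
    "five_utr",
    "three_utr",
    "exon",
    "intron",
    "proximal_promoter",
    "upstream_1kb",
    "upstream_1to2kb",
    "downstream_1kb",
    "intergenic",
]

PROMOTER_UP = 1000     # proximal promoter: 1 kb upstream ...
PROMOTER_DOWN = 200    # ... through 200 bp downstream of the TSS


def _flank(gene, up_from: int, up_to: int, downstream: bool, genome_len: int) -> GenomicInterval | None:
    """Strand-aware flanking interval of a gene, clipped to the chromosome."""
    chrom = gene.interval.chrom
    if gene.strand != "-":
        if downstream:
            s, e = gene.interval.end, gene.interval.end + up_to
        else:
            s, e = gene.interval.start - up_to, gene.interval.start - up_from
    else:
        if downstream:
            s, e = gene.interval.start - up_to, gene.interval.start
        else:
            s, e = gene.interval.end + up_from, gene.interval.end + up_to
    s, e = max(0, s), min(genome_len, e)
    return GenomicInterval(chrom, s, e, gene.strand) if e > s else None


def feature_spaces(annotation: AnnotationSet, genome: GenomeModel) -> dict[str, list[GenomicInterval]]:
    """Per-feature interval lists (non-exclusive genomic spaces)."""
    spaces: dict[str, list[GenomicInterval]] = {lab: [] for lab in FEATURE_LABELS if lab != "intergenic"}
    for g in annotation.genes:
        L = genome.length(g.interval.chrom)
        spaces["five_utr"].extend(g.five_utr)
        spaces["three_utr"].extend(g.three_utr)
        spaces["exon"].extend(g.exons)
        spaces["intron"].extend(g.introns())
        # promoter: 1 kb upstream through PROMOTER_DOWN into the gene
        if g.strand != "-":
            s, e = g.interval.start - PROMOTER_UP, g.interval.start + PROMOTER_DOWN
        else:
            s, e = g.interval.end - PROMOTER_DOWN, g.interval.end + PROMOTER_UP
        s, e = max(0, s), min(L, e)
        if e > s:
            spaces["proximal_promoter"].append(GenomicInterval(g.interval.chrom, s, e, g.strand))
        for lab, (a, b, down) in {
            "upstream_1kb": (0, 1000, False),
            "upstream_1to2kb": (1000, 2000, False),
            "downstream_1kb": (0, 1000, True),
        }.items():
            iv = _flank(g, a, b, down, L)
            if iv is not None:
                spaces[lab].append(iv)
    return spaces


def assign_feature(chrom: str, midpoint: int, annotation: AnnotationSet,
                   genome: GenomeModel, _spaces=None) -> str:
    """Exclusive feature label of a point, by fixed precedence."""
    if not (0 <= midpoint < genome.length(chrom)):
        raise ValueError(f"midpoint {chrom}:{midpoint} outside genome")
    spaces = _spaces if _spaces is not None else _merged_spaces(annotation, genome)
    for lab in FEATURE_LABELS[:-1]:
        if ivt.point_in_any(chrom, midpoint, spaces[lab]):
            return lab
    return "intergenic"


def _merged_spaces(annotation: AnnotationSet, genome: GenomeModel):
    return {
        lab: {c: ivt.merge(a) for c, a in ivt.by_chrom(ivs).items()}
        for lab, ivs in feature_spaces(annotation, genome).items()
    }


def feature_density(segments, annotation: AnnotationSet, genome: GenomeModel) -> pd.DataFrame:
    """Midpoint density per genomic feature, normalized per 10 kb of feature space.

    Membership is non-exclusive: a midpoint inside both an exon and a 5' UTR
    counts toward both features. Features with zero genomic space get NaN.
    """
    ivs = segments.intervals() if isinstance(segments, SegmentSet) else list(segments)
    mids = [(iv.chrom, iv.midpoint) for iv in ivs]
    spaces = feature_spaces(annotation, genome)
    merged = {lab: {c: ivt.merge(a) for c, a in ivt.by_chrom(v).items()} for lab, v in spaces.items()}
    rows = []
    for lab in FEATURE_LABELS[:-1]:
        space_bp = ivt.union_bp(spaces[lab])
        n = sum(ivt.point_in_any(c, m, merged[lab]) for c, m in mids)
        density = n / (space_bp / 1e4) if space_bp else np.nan
        rows.append({"feature": lab, "midpoints": n, "space_bp": space_bp, "per_10kb": density})
    return pd.DataFrame(rows)


def nearest_gene_distance(midpoints: list[tuple[str, int]], genes) -> np.ndarray:
    """Distance from each point to the closest gene boundary (0 if inside)."""
    merged = {c: ivt.merge(a) for c, a in ivt.by_chrom([g.interval for g in genes]).items()}
    out = []
    for chrom, pos in midpoints:
        d = ivt.nearest_gap(chrom, pos, merged)
        if d is None:
            raise ValueError(f"no genes on chromosome {chrom!r}")
        out.append(d)
    return np.array(out, dtype=float)


def gap_null(genes) -> np.ndarray:
    """Null distances: midpoints of the gaps between sequential genes, scored identically."""
    merged = {c: ivt.merge(a) for c, a in ivt.by_chrom([g.interval for g in genes]).items()}
    mids = []
    for chrom, arr in merged.items():
        for (s1, e1), (s2, e2) in zip(arr, arr[1:]):
            if s2 > e1:
                mids.append((chrom, (e1 + s2) // 2))
    return nearest_gene_distance(mids, genes)


def distance_test(observed: np.ndarray, null: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test comparing two distance samples."""
    t, p = stats.ttest_ind(observed, null, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    empirical_p: float
    n_perm: int


def _shift_points(points: np.ndarray, offset: int, length: int) -> np.ndarray:
    return (points + offset) % length


def permutation_enrichment(query, reference, genome: GenomeModel, n: int = 1000,
                           seed: int = 0, statistic: str = "midpoint") -> EnrichmentResult:
    """Circular-shift permutation test of query/reference overlap.

    Each permutation shifts all query regions of a chromosome by one uniform
    offset with wrap-around, preserving inter-region spacing. The statistic
    is the number of query midpoints inside the reference (default) or the
    base-pair overlap (``statistic='bp'``). The empirical p-value uses the
    (1 + #{null >= observed}) / (n + 1) estimator.
    """
    if n <= 0:
        raise ValueError("number of permutations must be positive")
    if statistic not in ("midpoint", "bp"):
        raise ValueError(f"unknown statistic {statistic!r}")
    q_ivs = query.intervals() if isinstance(query, SegmentSet) else list(query)
    r_ivs = reference.intervals() if isinstance(reference, SegmentSet) else list(reference)
    ref_merged = {c: ivt.merge(a) for c, a in ivt.by_chrom(r_ivs).items()}
    rng = np.random.default_rng(seed)

    def midpoint_stat(per_chrom_mids):
        return sum(
            int(ivt.point_in_any(c, int(m), ref_merged))
            for c, mids in per_chrom_mids.items() for m in mids
        )

    def bp_stat(ivs):
        return ivt.intersect_bp(ivs, r_ivs)

    q_by = {}
    for iv in q_ivs:
        q_by.setdefault(iv.chrom, []).append(iv)

    if statistic == "midpoint":
        base = {c: np.array([iv.midpoint for iv in ivs]) for c, ivs in q_by.items()}
        observed = midpoint_stat(base)
    else:
        observed = bp_stat(q_ivs)

    null = np.empty(n)
    for k in range(n):
        if statistic == "midpoint":
            shifted = {
                c: _shift_points(m, int(rng.integers(genome.length(c))), genome.length(c))
                for c, m in base.items()
            }
            null[k] = midpoint_stat(shifted)
        else:
            shifted_ivs = []
            for c, ivs in q_by.items():
                L = genome.length(c)
                off = int(rng.integers(L))
                for iv in ivs:
                    s, e = (iv.start + off) % L, (iv.end + off) % L
                    if s < e:
                        shifted_ivs.append(GenomicInterval(c, s, e, "."))
                    else:  # wraps the origin: split
                        shifted_ivs.append(GenomicInterval(c, s, L, "."))
                        if e > 0:
                            shifted_ivs.append(GenomicInterval(c, 0, e, "."))
            null[k] = bp_stat(shifted_ivs)

    p = (1 + int(np.sum(null >= observed))) / (n + 1)
    return EnrichmentResult(float(observed), float(null.mean()),
                            float(null.std(ddof=0)), p, n)


def chip_concordance(peaks_a, peaks_b, mode: str = "summit300",
                     max_summit_dist: int = 300) -> SegmentSet:
    """High-confidence ChIP peaks from two replicates.

    ``summit300``: keep pairs whose summits (peak midpoints) lie within
    ``max_summit_dist`` bp; emit the midpoint of the two summits plus/minus
    half the mean of the two peak spans. ``reciprocal50``: keep pairs whose
    overlap covers at least 50% of the smaller peak; emit the union span.
    Each peak is used at most once (greedy nearest-first pairing).
    """
    if mode not in ("summit300", "reciprocal50"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = []
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.chrom != b.chrom:
                continue
            if mode == "summit300":
                d = abs(a.midpoint - b.midpoint)
                if d <= max_summit_dist:
                    pairs.append((d, i, j))
            else:
                ov = min(a.end, b.end) - max(a.start, b.start)
                smaller = min(len(a), len(b))
                if ov >= 0.5 * smaller:
                    pairs.append((-ov, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    segs = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = peaks_a[i], peaks_b[j]
        if mode == "summit300":
            center = (a.midpoint + b.midpoint) // 2
            half = round((len(a) + len(b)) / 4)
            iv = GenomicInterval(a.chrom, max(0, center - half), center + max(half, 1), ".")
        else:
            iv = GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end), ".")
        segs.append(Segment(iv, "+", 0.0))
    segs.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return SegmentSet(segs, f"chip_{mode}")


def cobound(peaks1, peaks2, max_mid_dist: int = 500) -> SegmentSet:
    """Co-bound regions: peak pairs with midpoints within ``max_mid_dist`` bp."""
    ivs1 = peaks1.intervals() if isinstance(peaks1, SegmentSet) else list(peaks1)
    ivs2 = peaks2.intervals() if isinstance(peaks2, SegmentSet) else list(peaks2)
    segs = []
    for a in ivs1:
        for b in ivs2:
            if a.chrom == b.chrom and abs(a.midpoint - b.midpoint) <= max_mid_dist:
                iv = GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end), ".")
                segs.append(Segment(iv, "+", 0.0))
    return SegmentSet(segs, "cobound")


def overlap_with(segments, hs) -> float:
    """Fraction of segments whose interval intersects any HS region."""
    ivs = segments.intervals() if isinstance(segments, SegmentSet) else list(segments)
    hs_ivs = hs.intervals() if isinstance(hs, SegmentSet) else list(hs)
    if not ivs:
        return 0.0
    hs_by = {c: ivt.merge(a) for c, a in ivt.by_chrom(hs_ivs).items()}
    n = 0
    for iv in ivs:
        arr = hs_by.get(iv.chrom)
        if arr is None or len(arr) == 0:
            continue
        # merged intervals are disjoint and sorted, so among those starting
        # before iv.end only the last can still reach past iv.start
        k = int(np.searchsorted(arr[:, 0], iv.end, side="left"))
        if k > 0 and arr[k - 1, 1] > iv.start:
            n += 1
    return n / len(ivs)


def motif_proximity(motifs_a, motifs_b, window: int = 50):
    """Distances between motif occurrences and combinatorial modules.

    For each A motif, the distance is the minimum end-to-start gap to any B
    motif (0 when overlapping). When the distance is at most ``window`` bp a
    module spanning both motifs is emitted.
    """
    distances = []
    modules = []
    for a in motifs_a:
        best = None
        best_b = None
        for b in motifs_b:
            if a.chrom != b.chrom:
                continue
            gap = ivt.interval_gap(a, b)
            if best is None or gap < best:
                best, best_b = gap, b
        if best is None:
            distances.append(np.nan)
            continue
        distances.append(best)
        if best <= window:
            iv = GenomicInterval(a.chrom, min(a.start, best_b.start),
                                 max(a.end, best_b.end), ".")
            modules.append(Segment(iv, "+", 0.0))
    return np.array(distances, dtype=float), SegmentSet(modules, "motif_modules")


def term_enrichment(selected_genes, universe, term_map: dict[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of terms with BH correction.

    For each term with K annotated genes in a universe of N, and k of the n
    selected genes annotated, p = P(X >= k) under the hypergeometric null;
    q is the Benjamini-Hochberg adjustment across terms.
    """
    from .gwas import bh_adjust

    selected = set(selected_genes)
    uni = set(universe)
    if not selected <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(uni), len(selected)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & uni
        K = len(members)
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = []
    return df
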