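"""Long non-coding RNA annotation and co-expression.

A transcript survives the lncRNA filter cascade when it is at least 200 nt,
its longest ORF encodes at most 100 aa, it carries no protein-domain,
coding-potential or structural-RNA flag, hosts fewer than 20 distinct small
RNA reads, and sums to at least 10 TPM across stages. Retained lncRNAs are
classified by position relative to protein-coding genes, scored for stage
specificity with a normalized Shannon-entropy metric, and paired with their
closest gene by biweight midcorrelation of log-transformed expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import intervals as ivt
from .model import AnnotationSet, GenomicInterval

__all__ = [
    "TranscriptRecord",
    "longest_orf",
    "smallrna_hosting",
    "filter_cascade",
    "classify_lncrna",
    "entropy_specificity",
    "bicor",
    "pair_coexpression",
    "cluster_modules",
]

FILTER_ORDER = [
    "min_length",        # < 200 nt
    "orf_length",        # longest ORF > 100 aa
    "domain_hit",        # Pfam-style protein-domain homology flag
    "coding_potential",  # coding-potential classifier flag
    "structural_rna",    # structural-RNA homology flag
    "smallrna_host",     # hosts >= 20 distinct small RNA reads
    "min_expression",    # sum TPM across stages < 10
]

STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class TranscriptRecord:
    """All inputs the filter cascade consumes, for one assembled transcript."""

    id: str
    sequence: str
    interval: GenomicInterval | None = None
    domain_hit: bool = False
    coding_potential: bool = False
    structural_rna: bool = False
    distinct_smallrna: int = 0
    tpm: np.ndarray = field(default_factory=lambda: np.zeros(8))

    @property
    def length(self) -> int:
        return len(self.sequence)


def longest_orf(sequence: str) -> int:
    """Longest ORF over the three forward frames, in amino acids.

    An ORF runs ATG..stop with the stop in frame; the peptide length counts
    the initial Met and excludes the stop. ORFs lacking an in-frame stop do
    not count.
    """
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i: i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def smallrna_hosting(sequence: str, smallrna_reads) -> int:
    """Count distinct 18-34 nt small RNA reads hosted by a transcript.

    A read is hosted when its sequence occurs as an exact substring of the
    transcript in either orientation; read multiplicity is ignored.
    """
    seq = sequence.upper()
    rc = reverse_complement(seq)
    hosted = set()
    for read in smallrna_reads:
        r = read.upper()
        if not (18 <= len(r) <= 34):
            continue
        if r in seq or r in rc:
            hosted.add(r)
    return len(hosted)


def filter_cascade(records) -> tuple[list[TranscriptRecord], dict[str, int]]:
    """Apply the lncRNA filter cascade; attribute drops to the first failing filter."""
    tally = {name: 0 for name in FILTER_ORDER}
    retained = []
    for rec in records:
        if rec.length < 200:
            tally["min_length"] += 1
        elif longest_orf(rec.sequence) > 100:
            tally["orf_length"] += 1
        elif rec.domain_hit:
            tally["domain_hit"] += 1
        elif rec.coding_potential:
            tally["coding_potential"] += 1
        elif rec.structural_rna:
            tally["structural_rna"] += 1
        elif rec.distinct_smallrna >= 20:
            tally["smallrna_host"] += 1
        elif float(np.sum(rec.tpm)) < 10:
            tally["min_expression"] += 1
        else:
            retained.append(rec)
    return retained, tally


def classify_lncrna(lnc_iv: GenomicInterval, annotation: AnnotationSet) -> str:
    """Positional class of a retained lncRNA relative to protein-coding genes.

    Precedence: antisense (opposite-strand overlap of a gene) over genic
    subtypes (entirely exonic, entirely intronic, or exon-intron spanning)
    over intergenic distance bins (<=2 kb, <=10 kb, >10 kb to the closest
    gene boundary).
    """
    overlapping = [g for g in annotation.genes if g.interval.overlaps(lnc_iv)]
    for g in overlapping:
        if lnc_iv.strand in ("+", "-") and g.strand in ("+", "-") and lnc_iv.strand != g.strand:
            return "antisense"
    for g in overlapping:
        exonic = {c: ivt.merge(a) for c, a in ivt.by_chrom(g.exons).items()}
        within = lambda ivs: any(
            s <= lnc_iv.start and lnc_iv.end <= e
            for s, e in ivs.get(lnc_iv.chrom, np.empty((0, 2)))
        )
        if within(exonic):
            return "exonic"
        intronic = {c: ivt.merge(a) for c, a in ivt.by_chrom(g.introns()).items()}
        if within(intronic):
            return "intronic"
        if g.interval.start <= lnc_iv.start and lnc_iv.end <= g.interval.end:
            return "exon_intron"
    merged = {c: ivt.merge(a) for c, a in ivt.by_chrom([g.interval for g in annotation.genes]).items()}
    d = ivt.nearest_gap(lnc_iv.chrom, lnc_iv.midpoint, merged)
    if d is None:
        return "intergenic_far"
    # distance from the lncRNA edge rather than midpoint
    d = min(
        x for x in (
            ivt.nearest_gap(lnc_iv.chrom, lnc_iv.start, merged),
            ivt.nearest_gap(lnc_iv.chrom, lnc_iv.end - 1, merged),
        ) if x is not None
    )
    if d <= 2000:
        return "intergenic_2kb"
    if d <= 10000:
        return "intergenic_10kb"
    return "intergenic_far"


def entropy_specificity(tpm_vector) -> float:
    """Normalized Shannon-entropy specificity of an expression profile.

    SH = 1 - H/log2(n) where H is the entropy of the TPM proportions:
    1 for one-hot (stage-specific), 0 for uniform (broad) expression.
    """
    v = np.asarray(tpm_vector, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative TPM")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero expression profile has undefined specificity")
    p = v / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return 1.0 - h / np.log2(len(v))


def bicor(x, y) -> float:
    """Biweight midcorrelation, robust to outlying stages.

    Observations are median-centred and weighted by Tukey biweights
    w = (1 - u^2)^2 for |u| < 1, u = (x - med) / (9 MAD) with the unscaled
    MAD. Zero MAD in either vector falls back to Pearson with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")

    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        a = (v - med) * w
        return a / np.sqrt(np.sum(a**2))

    wx, wy = weighted(x), weighted(y)
    if wx is None or wy is None:
        warnings.warn("zero MAD; falling back to Pearson correlation")
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            raise ValueError("constant vector: correlation undefined")
        return float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(np.sum(wx * wy), -1.0, 1.0))


def _closest_gene(lnc_iv: GenomicInterval, genes):
    best, best_d = None, None
    for g in genes:
        if g.interval.chrom != lnc_iv.chrom:
            continue
        d = ivt.interval_gap(lnc_iv, g.interval)
        if best_d is None or (d, g.id) < (best_d, best.id):
            best, best_d = g, d
    return best, best_d


PAIRING_CLASSES = ("intronic", "intergenic_2kb", "intergenic_10kb", "intergenic_far")


def pair_coexpression(lncs, genes, annotation: AnnotationSet,
                      gene_tpm: dict[str, np.ndarray], cutoff: float = 0.8,
                      log_transform: bool = True) -> pd.DataFrame:
    """Co-expression pairs between lncRNAs and their closest coding gene.

    ``lncs`` are retained TranscriptRecords with intervals and 8-stage TPM.
    Candidate pairs are formed per positional class (intronic and the three
    intergenic bins) with the closest gene; expression is log2(TPM+1)
    transformed before the biweight midcorrelation, and pairs with
    |bicor| > cutoff are kept.
    """
    rows = []
    for lnc in lncs:
        if lnc.interval is None:
            continue
        cls = classify_lncrna(lnc.interval, annotation)
        if cls not in PAIRING_CLASSES:
            continue
        gene, dist = _closest_gene(lnc.interval, annotation.genes)
        if gene is None or gene.id not in gene_tpm:
            continue
        x = np.asarray(lnc.tpm, dtype=float)
        y = np.asarray(gene_tpm[gene.id], dtype=float)
        if log_transform:
            x, y = np.log2(x + 1), np.log2(y + 1)
        r = bicor(x, y)
        if abs(r) > cutoff:
            rows.append({
                "lncrna": lnc.id, "gene": gene.id, "class": cls,
                "bicor": r, "distance_bp": dist,
            })
    return pd.DataFrame(rows, columns=["lncrna", "gene", "class", "bicor", "distance_bp"])


def cluster_modules(pairs: pd.DataFrame, lnc_tpm: dict[str, np.ndarray],
                    gene_tpm: dict[str, np.ndarray], cut_height: float = 0.25) -> pd.DataFrame:
    """Hierarchical module assignment of co-expressed pairs.

    Each pair's profile is the mean of the z-scored log2(TPM+1) profiles of
    its lncRNA and gene; pairs are agglomeratively clustered with complete
    (maximum) linkage on distance 1 - bicor and the tree cut at
    ``cut_height``. Input order does not affect assignments.
    """
    if len(pairs) == 0:
        return pairs.assign(module=pd.Series(dtype=int))
    pairs = pairs.sort_values(["lncrna", "gene"]).reset_index(drop=True)
    if len(pairs) == 1:
        return pairs.assign(module=[1])

    def z(v):
        v = np.log2(np.asarray(v, dtype=float) + 1)
        s = v.std()
        return (v - v.mean()) / s if s else v - v.mean()

    profiles = np.array([
        (z(lnc_tpm[r.lncrna]) + z(gene_tpm[r.gene])) / 2 for r in pairs.itertuples()
    ])
    m = len(profiles)
    dist = np.zeros(m * (m - 1) // 2)
    k = 0
    for i in range(m):
        for j in range(i + 1, m):
            dist[k] = 1 - bicor(profiles[i], profiles[j])
            k += 1
    tree = linkage(dist, method="complete")
    labels = fcluster(tree, t=cut_height, criterion="distance")
    return pairs.assign(module=labels)
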