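"""Seed-controlled synthetic inputs with the statistical structure the
pipeline assumes, plus ground-truth records for recovery testing.

The generators emulate the study conditions of a paired light/heavy MNase
digest experiment on inflorescence primordia: accessible (hypersensitive)
sites enriched for sub-131-bp fragments in the light digest over a
nucleosomal background, TF footprints as tight clusters of small-fragment
centers, gene models with exons/UTRs, stage-wise expression with planted
co-expressed lncRNA-gene pairs, transcripts with controlled ORF content and
small-RNA hosting, a CHH-methylation island upstream of TSSs, and marker
p-values enriched for signal inside accessible regions.

Every generator takes an explicit seed and is fully deterministic; no
global RNG state is touched. Truth is serialized to JSON so downstream
recovery tests can run from files alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import (
    AnnotationSet,
    FragmentSet,
    GeneModel,
    GenomeModel,
    GenomicInterval,
    WindowedSignal,
)

__all__ = [
    "TruthSet",
    "make_genome",
    "make_annotation",
    "simulate_fragments",
    "simulate_expression",
    "simulate_transcripts",
    "default_transcript_design",
    "simulate_markers",
    "simulate_methylation",
    "simulate_dns_pair",
]

# fragment-length model (bp): mononucleosomal background vs sub-nucleosomal
BG_LEN_MEAN, BG_LEN_SD, BG_LEN_RANGE = 147, 10, (100, 220)
SMALL_LEN_MEAN, SMALL_LEN_SD, SMALL_LEN_RANGE = 80, 15, (30, 130)


@dataclass
class TruthSet:
    """Ground truth for planted structure, all recoverable by id/coordinate."""

    planted_hs: list[tuple[str, int, int]] = field(default_factory=list)
    planted_footprints: list[tuple[str, int]] = field(default_factory=list)
    differential_genes: list[tuple[str, str]] = field(default_factory=list)
    true_lncrna_labels: dict[str, str] = field(default_factory=dict)  # id -> "pass" or failing filter
    coexpressed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    signal_markers: list[str] = field(default_factory=list)

    def hs_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(c, s, e, ".") for c, s, e in self.planted_hs]

    def to_json(self, path) -> None:
        def _plain(o):
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(f"cannot serialize {type(o)}")

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_plain)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_hs=[tuple(x) for x in d["planted_hs"]],
            planted_footprints=[tuple(x) for x in d["planted_footprints"]],
            differential_genes=[tuple(x) for x in d["differential_genes"]],
            true_lncrna_labels=dict(d["true_lncrna_labels"]),
            coexpressed_pairs=[(a, b, float(r)) for a, b, r in d["coexpressed_pairs"]],
            signal_markers=list(d["signal_markers"]),
        )


def make_genome(n_chrom: int = 2, chrom_length: int = 1_000_000, seed: int = 0) -> GenomeModel:
    """A genome of equally sized chromosomes named chr1..chrN."""
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    if n_chrom <= 0:
        raise ValueError("need at least one chromosome")
    return GenomeModel(tuple((f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom)))


def _place_nonoverlapping(rng, length: int, sizes: list[int], min_gap: int, margin: int) -> list[int]:
    """Random starts for blocks of given sizes, in order, min_gap apart."""
    k = len(sizes)
    if k == 0:
        return []
    slack = length - (sum(sizes) + min_gap * (k - 1) + 2 * margin)
    if slack < 0:
        raise ValueError("features do not fit on the chromosome")
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    starts = []
    base = margin
    for i, size in enumerate(sizes):
        starts.append(base + int(cuts[i]))
        base += size + min_gap
    return starts


def make_annotation(genome: GenomeModel, n_genes: int = 60, n_tes: int = 40,
                    seed: int = 0, min_gap: int = 2000, n_hs: int = 200,
                    hs_width: int = 300, n_footprints: int = 50,
                    promoter_hs_frac: float = 0.25) -> tuple[AnnotationSet, TruthSet]:
    """Gene/TE annotation plus planted hypersensitive sites and footprints.

    Genes are non-overlapping with 1-5 exons and terminal UTRs, strands
    uniform; TEs sit in intergenic space with retrotransposon/DNA class
    labels. HS sites of ``hs_width`` bp are planted clear of each other;
    a fraction ``promoter_hs_frac`` of them sit immediately upstream of a
    gene TSS (strand-aware, at most one per gene) to mirror the
    promoter-biased distribution of accessible chromatin, the rest are
    intergenic. ``n_footprints`` of the sites carry a footprint at their
    central base.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    n_prom_hs = min(n_genes, int(round(promoter_hs_frac * n_hs)))
    per_chrom_genes = _split_count(n_genes, [l for _, l in chroms])
    per_chrom_hs = _split_count(n_hs - n_prom_hs, [l for _, l in chroms])
    per_chrom_tes = _split_count(n_tes, [l for _, l in chroms])

    genes: list[GeneModel] = []
    hs: list[tuple[str, int, int]] = []
    tes: list[GenomicInterval] = []
    gi = 0
    for (chrom, length), ng, nh, nt in zip(chroms, per_chrom_genes, per_chrom_hs, per_chrom_tes):
        gene_sizes = list(rng.integers(1500, 4001, size=ng))
        te_sizes = list(rng.integers(300, 1501, size=nt))
        sizes = gene_sizes + [hs_width] * nh + te_sizes
        kinds = ["gene"] * ng + ["hs"] * nh + ["te"] * nt
        order = rng.permutation(len(sizes))
        sizes = [sizes[i] for i in order]
        kinds = [kinds[i] for i in order]
        starts = _place_nonoverlapping(rng, length, sizes, min_gap, margin=3000)
        for start, size, kind in zip(starts, sizes, kinds):
            if kind == "gene":
                gi += 1
                genes.append(_random_gene(rng, f"gene{gi:04d}", chrom, start, start + size))
            elif kind == "hs":
                hs.append((chrom, start, start + size))
            else:
                klass = "retrotransposon" if rng.random() < 0.5 else "DNA"
                strand = rng.choice(["+", "-", "."])
                # unassigned-strand TEs are treated as sense ('+')
                strand = "+" if strand == "." else str(strand)
                tes.append(GenomicInterval(chrom, start, start + size, strand, name=klass))

    # promoter-proximal HS: immediately upstream of the TSS, strand-aware,
    # inside the inter-feature gap the min_gap placement guarantees
    if n_prom_hs:
        for g in (genes[i] for i in rng.choice(len(genes), size=n_prom_hs, replace=False)):
            if g.strand != "-":
                s = g.interval.start - 50 - hs_width
            else:
                s = g.interval.end + 50
            hs.append((g.interval.chrom, s, s + hs_width))
    hs.sort()

    fp_sites = rng.choice(len(hs), size=min(n_footprints, len(hs)), replace=False)
    footprints = [
        (hs[i][0], (hs[i][1] + hs[i][2]) // 2) for i in sorted(fp_sites.tolist())
    ]
    truth = TruthSet(planted_hs=hs, planted_footprints=footprints)
    return AnnotationSet(genes=genes, tes=tes), truth


def _split_count(n: int, lengths: list[int]) -> list[int]:
    total = sum(lengths)
    out = [n * l // total for l in lengths]
    i = 0
    while sum(out) < n:
        out[i % len(out)] += 1
        i += 1
    return out


def _random_gene(rng, gid: str, chrom: str, start: int, end: int) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    span = end - start
    n_exons = int(rng.integers(1, 6))
    # pick exon/intron boundaries: 2*(n_exons-1) interior cut points
    if n_exons == 1:
        exons = [(start, end)]
    else:
        cuts = np.sort(rng.choice(np.arange(1, span - 1), size=2 * (n_exons - 1), replace=False))
        bounds = [0, *cuts.tolist(), span]
        exons = [(start + bounds[2 * i], start + bounds[2 * i + 1]) for i in range(n_exons)]
        exons = [(s, e) for s, e in exons if e > s]
    exon_ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    # terminal UTRs inside the first/last exon (strand-aware)
    first, last = exon_ivs[0], exon_ivs[-1]
    utr5_len = min(len(first) // 3, 200)
    utr3_len = min(len(last) // 3, 200)
    if strand == "+":
        five = (GenomicInterval(chrom, first.start, first.start + utr5_len, strand),) if utr5_len else ()
        three = (GenomicInterval(chrom, last.end - utr3_len, last.end, strand),) if utr3_len else ()
    else:
        five = (GenomicInterval(chrom, last.end - utr5_len, last.end, strand),) if utr5_len else ()
        three = (GenomicInterval(chrom, first.start, first.start + utr3_len, strand),) if utr3_len else ()
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand), exon_ivs, five, three)


def simulate_fragments(genome: GenomeModel, truth: TruthSet, digest: str = "light",
                       n_fragments: int = 200_000, enrichment: float = 8.0,
                       seed: int = 0, footprint_frac: float = 0.5,
                       replicate: str = "rep1") -> FragmentSet:
    """MNase fragments with accessible-site enrichment in the light digest.

    Background fragments have uniform centers and mononucleosomal lengths
    (Normal(147, 10) clipped to [100, 220]). In the light digest, fragment
    centers fall inside planted HS space with probability
    min(1, enrichment * hs_fraction) (background centers fill the
    complement), and in-HS fragments draw sub-nucleosomal lengths
    (Normal(80, 15) clipped to [30, 130]) with probability 1 - 1/enrichment,
    so ``enrichment=1`` reduces exactly to background. A fraction
    ``footprint_frac`` of small in-HS fragments at footprint-bearing sites
    have centers tightly clustered (SD 4 bp) on the footprint. The heavy
    digest gets no excess at HS sites.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if digest not in ("light", "heavy"):
        raise ValueError(f"digest must be 'light' or 'heavy', got {digest!r}")
    rng = np.random.default_rng(seed)

    chrom_names = genome.names
    chrom_lengths = np.array([genome.length(c) for c in chrom_names], dtype=np.int64)
    hs = truth.planted_hs
    hs_bp = sum(e - s for _, s, e in hs)
    hs_frac = hs_bp / genome.total_bp
    fp_by_site = {}
    fp_set = set(truth.planted_footprints)
    for i, (c, s, e) in enumerate(hs):
        center = (c, (s + e) // 2)
        if center in fp_set:
            fp_by_site[i] = center[1]

    p_hs = min(1.0, enrichment * hs_frac) if (digest == "light" and hs_bp) else 0.0
    q_small = 1 - 1 / enrichment
    n_hs_frag = int(round(n_fragments * p_hs))

    intervals: list[GenomicInterval] = []

    def clip_fragment(chrom_i: int, center: int, length: int) -> GenomicInterval:
        L = int(chrom_lengths[chrom_i])
        start = center - length // 2
        start = min(max(0, start), L - length)
        return GenomicInterval(chrom_names[chrom_i], start, start + length, ".")

    # HS-targeted fragments (light digest only)
    if n_hs_frag:
        sizes = np.array([e - s for _, s, e in hs])
        site_idx = rng.choice(len(hs), size=n_hs_frag, p=sizes / sizes.sum())
        small = rng.random(n_hs_frag) < q_small
        lens = np.where(
            small,
            np.clip(np.round(rng.normal(SMALL_LEN_MEAN, SMALL_LEN_SD, n_hs_frag)), *SMALL_LEN_RANGE),
            np.clip(np.round(rng.normal(BG_LEN_MEAN, BG_LEN_SD, n_hs_frag)), *BG_LEN_RANGE),
        ).astype(int)
        at_fp = small & np.array([i in fp_by_site for i in site_idx]) \
            & (rng.random(n_hs_frag) < footprint_frac)
        u = rng.random(n_hs_frag)
        fp_jitter = np.round(rng.normal(0, 4, n_hs_frag)).astype(int)
        for k in range(n_hs_frag):
            c, s, e = hs[site_idx[k]]
            ci = chrom_names.index(c)
            if at_fp[k]:
                center = int(np.clip(fp_by_site[site_idx[k]] + fp_jitter[k], s, e - 1))
            else:
                center = s + int(u[k] * (e - s))
            intervals.append(clip_fragment(ci, center, int(lens[k])))

    # background fragments
    n_bg = n_fragments - n_hs_frag
    if n_bg:
        lens = np.clip(np.round(rng.normal(BG_LEN_MEAN, BG_LEN_SD, n_bg)), *BG_LEN_RANGE).astype(int)
        ci = rng.choice(len(chrom_names), size=n_bg, p=chrom_lengths / chrom_lengths.sum())
        centers = (rng.random(n_bg) * chrom_lengths[ci]).astype(np.int64)
        if p_hs > 0:
            # background fills the complement of HS space: resample any
            # center landing inside a planted site
            from . import intervals as ivt
            merged = {c: ivt.merge(a) for c, a in ivt.by_chrom(truth.hs_intervals()).items()}
            for k in range(n_bg):
                chrom = chrom_names[ci[k]]
                while ivt.point_in_any(chrom, int(centers[k]), merged):
                    centers[k] = int(rng.random() * chrom_lengths[ci[k]])
        for k in range(n_bg):
            intervals.append(clip_fragment(int(ci[k]), int(centers[k]), int(lens[k])))

    return FragmentSet(intervals, digest=digest, replicate=replicate)


def simulate_expression(transcript_ids, n_stages: int = 8, pairs=(), seed: int = 0,
                        max_redraws: int = 100) -> pd.DataFrame:
    """Stage-wise TPM matrix with planted co-expressed pairs.

    ``pairs`` is a list of (lncrna_id, gene_id, target_r); each planted pair
    is redrawn (deterministically) until the realized Pearson correlation of
    its TPM profiles reaches the target magnitude with the target sign.
    Unpaired transcripts are mutually independent log-normal profiles.
    """
    rng = np.random.default_rng(seed)
    ids = list(transcript_ids)
    paired_ids = {i for a, b, _ in pairs for i in (a, b)}
    expr: dict[str, np.ndarray] = {}
    for tid in ids:
        if tid not in paired_ids:
            expr[tid] = np.exp(rng.normal(1.5, 1.0, n_stages))
    for a, b, target in pairs:
        if not 0 < abs(target) <= 1:
            raise ValueError(f"target correlation {target} out of range")
        noise_sd = 0.5 * np.sqrt(1 / target**2 - 1)
        for _ in range(max_redraws):
            latent = rng.normal(2.0, 1.0, n_stages)
            xa = np.exp(latent + rng.normal(0, noise_sd, n_stages))
            lb = latent if target > 0 else (2 * latent.mean() - latent)
            xb = np.exp(lb + rng.normal(0, noise_sd, n_stages))
            r = np.corrcoef(xa, xb)[0, 1]
            if (target > 0 and r >= target) or (target < 0 and r <= target):
                expr[a], expr[b] = xa, xb
                break
        else:
            raise RuntimeError(f"could not realize target correlation {target} for ({a}, {b})")
    df = pd.DataFrame(
        {f"stage{i + 1}": [expr[t][i] for t in ids] for i in range(n_stages)},
        index=pd.Index(ids, name="transcript"),
    )
    return df


def default_transcript_design() -> pd.DataFrame:
    """Twelve transcripts covering every cascade filter; exactly five pass."""
    rows = [
        # id, length, orf_aa, domain, coding, structural, n_smallrna, tpm_sum
        ("t01", 150, 0, False, False, False, 0, 20.0),    # fails min_length
        ("t02", 600, 120, False, False, False, 0, 20.0),  # fails orf_length
        ("t03", 400, 50, True, False, False, 0, 20.0),    # fails domain_hit
        ("t04", 400, 0, False, True, False, 0, 20.0),     # fails coding_potential
        ("t05", 400, 0, False, False, True, 0, 20.0),     # fails structural_rna
        ("t06", 400, 0, False, False, False, 25, 20.0),   # fails smallrna_host
        ("t07", 400, 0, False, False, False, 0, 5.0),     # fails min_expression
        ("t08", 200, 0, False, False, False, 0, 10.0),    # passes (length & TPM boundaries)
        ("t09", 400, 100, False, False, False, 0, 50.0),  # passes (ORF boundary)
        ("t10", 400, 0, False, False, False, 19, 30.0),   # passes (small RNA boundary)
        ("t11", 1000, 40, False, False, False, 0, 15.0),  # passes
        ("t12", 250, 0, False, False, False, 5, 12.0),    # passes
    ]
    return pd.DataFrame(rows, columns=[
        "id", "length", "orf_aa", "domain_hit", "coding_potential",
        "structural_rna", "n_smallrna", "tpm_sum",
    ])


_FAIL_OF = [
    ("length", lambda r: r.length < 200, "min_length"),
    ("orf", lambda r: r.orf_aa > 100, "orf_length"),
    ("domain", lambda r: r.domain_hit, "domain_hit"),
    ("coding", lambda r: r.coding_potential, "coding_potential"),
    ("struct", lambda r: r.structural_rna, "structural_rna"),
    ("srna", lambda r: r.n_smallrna >= 20, "smallrna_host"),
    ("tpm", lambda r: r.tpm_sum < 10, "min_expression"),
]

_NO_A = "CGT"


def _backbone(rng, n: int) -> list[str]:
    return [_NO_A[i] for i in rng.integers(0, 3, size=n)]


def simulate_transcripts(n: int | None = None, design_table: pd.DataFrame | None = None,
                         seed: int = 0, smallrna_len: int = 21):
    """Transcript sequences following a design table exactly.

    Sequences use an A-free backbone so the only ATG and stop codons are the
    ones planted for the designed longest ORF; hosted small RNAs are
    ``smallrna_len``-nt substrings extracted from each transcript. Returns
    (sequences, TranscriptRecords without intervals, small RNA reads, truth
    labels mapping id to "pass" or the first failing filter).
    """
    from .lncrna import TranscriptRecord

    if design_table is None:
        design_table = default_transcript_design()
    if n is not None:
        if n != len(design_table):
            raise ValueError("n does not match the design table")
    rng = np.random.default_rng(seed)

    seqs: dict[str, str] = {}
    records: list = []
    reads: list[str] = []
    labels: dict[str, str] = {}
    for row in design_table.itertuples():
        length = int(row.length)
        chars = _backbone(rng, length)
        orf_aa = int(row.orf_aa)
        if orf_aa > 0:
            block = ["A", "T", "G"] + _backbone(rng, 3 * (orf_aa - 1)) + ["T", "A", "A"]
            if len(block) > length:
                raise ValueError(f"{row.id}: ORF of {orf_aa} aa does not fit in {length} nt")
            # in-frame placement relative to the transcript start
            max_slot = (length - len(block)) // 3
            pos = 3 * int(rng.integers(0, max_slot + 1))
            chars[pos: pos + len(block)] = block
        seq = "".join(chars)
        seqs[row.id] = seq

        k = int(row.n_smallrna)
        if k:
            if length < smallrna_len + k:
                raise ValueError(f"{row.id}: cannot host {k} distinct small RNAs")
            hosted: set[str] = set()
            while len(hosted) < k:
                s = int(rng.integers(0, length - smallrna_len + 1))
                hosted.add(seq[s: s + smallrna_len])
            reads.extend(sorted(hosted))

        records.append(TranscriptRecord(
            id=row.id, sequence=seq,
            domain_hit=bool(row.domain_hit),
            coding_potential=bool(row.coding_potential),
            structural_rna=bool(row.structural_rna),
            distinct_smallrna=k,
            tpm=_dyadic_split(rng, float(row.tpm_sum), 8),
        ))
        label = "pass"
        for _, bad, name in _FAIL_OF:
            if bad(row):
                label = name
                break
        labels[row.id] = label

    # decoy reads hosted by nothing (contain A so they cannot match backbones)
    for _ in range(10):
        reads.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=smallrna_len)))
    return seqs, records, reads, labels


def _dyadic_split(rng, total: float, n: int) -> np.ndarray:
    """Split ``total`` into n parts that sum to it exactly in floating point."""
    w = rng.multinomial(64, np.full(n, 1 / n))
    while np.all(w == 0):  # unreachable, defensive
        w = rng.multinomial(64, np.full(n, 1 / n))
    return total * (w / 64.0)


def simulate_markers(genome: GenomeModel, hs_regions, n_markers: int = 50_000,
                     pi_signal: float = 0.3, effect: float = 0.2,
                     seed: int = 0) -> tuple[pd.DataFrame, TruthSet]:
    """GWAS marker table with signal planted inside accessible regions.

    Marker positions are uniform over the genome; p-values are Uniform(0,1]
    except that a fraction ``pi_signal`` of the markers falling inside
    ``hs_regions`` draw from Beta(effect, 1) with effect < 1 (right-skewed
    toward small p). Returns the table and a TruthSet listing the signal
    markers.
    """
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    if not 0 <= pi_signal <= 1:
        raise ValueError("pi_signal must be in [0, 1]")
    if pi_signal > 0 and not 0 < effect < 1:
        raise ValueError("effect must be in (0, 1)")
    from . import intervals as ivt

    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([genome.length(c) for c in names], dtype=np.int64)
    ci = rng.choice(len(names), size=n_markers, p=lengths / lengths.sum())
    pos = (rng.random(n_markers) * lengths[ci]).astype(np.int64)
    p = 1.0 - rng.random(n_markers)  # Uniform(0, 1]

    ivs = hs_regions.intervals() if hasattr(hs_regions, "intervals") else list(hs_regions)
    merged = {c: ivt.merge(a) for c, a in ivt.by_chrom(ivs).items()}
    signal_ids = []
    ids = [f"m{k + 1:06d}" for k in range(n_markers)]
    if pi_signal > 0:
        for k in range(n_markers):
            if ivt.point_in_any(names[ci[k]], int(pos[k]), merged) and rng.random() < pi_signal:
                p[k] = max(rng.beta(effect, 1.0), 1e-300)
                signal_ids.append(ids[k])
    df = pd.DataFrame({
        "id": ids,
        "chrom": [names[i] for i in ci],
        "pos": pos,
        "p": p,
    })
    return df, TruthSet(signal_markers=signal_ids)


def simulate_methylation(annotation: AnnotationSet, genome: GenomeModel,
                         island_params: dict | None = None, seed: int = 0,
                         cytosine_rate: float = 0.05) -> pd.DataFrame:
    """Per-cytosine methylation ratios with a CHH island upstream of TSSs.

    Baseline: CG/CHG are high in gene-distal background and depressed in
    gene bodies; CHH is uniformly low. An asymmetric CHH island of
    ``width`` bp immediately upstream of every gene TSS (strand-aware) is
    raised by ``height``. island_params keys: width (200), height (0.5),
    chh_background (0.05).
    """
    params = {"width": 200, "height": 0.5, "chh_background": 0.05}
    if island_params:
        params.update(island_params)
    rng = np.random.default_rng(seed)
    from . import intervals as ivt

    gene_space = {c: ivt.merge(a) for c, a in
                  ivt.by_chrom([g.interval for g in annotation.genes]).items()}
    islands = []
    for g in annotation.genes:
        if g.strand != "-":
            s, e = g.tss - params["width"], g.tss
        else:
            s, e = g.tss + 1, g.tss + 1 + params["width"]
        s = max(0, s)
        e = min(genome.length(g.interval.chrom), e)
        if e > s:
            islands.append(GenomicInterval(g.interval.chrom, s, e, "."))
    island_merged = {c: ivt.merge(a) for c, a in ivt.by_chrom(islands).items()}

    rows = []
    for chrom, length in genome.chromosomes:
        n_c = rng.poisson(cytosine_rate * length)
        positions = np.sort(rng.choice(length, size=min(n_c, length), replace=False))
        contexts = rng.choice(["CG", "CHG", "CHH"], size=len(positions), p=[0.3, 0.3, 0.4])
        for pos, ctx in zip(positions, contexts):
            genic = ivt.point_in_any(chrom, int(pos), gene_space)
            if ctx in ("CG", "CHG"):
                base = 0.15 if genic else 0.8
            else:
                base = params["chh_background"]
                if ivt.point_in_any(chrom, int(pos), island_merged):
                    base += params["height"]
            ratio = float(np.clip(base + rng.normal(0, 0.05), 0.0, 1.0))
            rows.append((chrom, int(pos), ctx, ratio))
    return pd.DataFrame(rows, columns=["chrom", "position", "context", "ratio"])


def simulate_dns_pair(genome: GenomeModel, genes, planted: dict[str, str],
                      offset: float = 3.0, noise_sd: float = 0.15,
                      width: int = 25, promoter_length: int = 500,
                      seed: int = 0) -> tuple[WindowedSignal, WindowedSignal, TruthSet]:
    """Paired tissue DNS tracks with planted differential promoters.

    Both tissues share a unit-SD baseline plus small independent noise;
    genes in ``planted`` (id -> 'tassel' or 'ear') have ``offset`` added to
    the windows covering the 500 bp upstream of their TSS in the named
    tissue, three baseline SDs by default.
    """
    rng = np.random.default_rng(seed)
    base = {c: rng.normal(0, 1, -(-l // width)) for c, l in genome.chromosomes}
    vt = {c: v + rng.normal(0, noise_sd, len(v)) for c, v in base.items()}
    ve = {c: v + rng.normal(0, noise_sd, len(v)) for c, v in base.items()}
    diffs = []
    for g in genes:
        direction = planted.get(g.id)
        if direction is None:
            continue
        if direction not in ("tassel", "ear"):
            raise ValueError(f"bad direction {direction!r} for gene {g.id}")
        chrom = g.interval.chrom
        L = genome.length(chrom)
        if g.strand != "-":
            lo, hi = max(0, g.tss - promoter_length), g.tss
        else:
            lo, hi = g.tss + 1, min(L, g.tss + 1 + promoter_length)
        i0, i1 = lo // width, -(-hi // width)
        (vt if direction == "tassel" else ve)[chrom][i0:i1] += offset
        diffs.append((g.id, direction))
    truth = TruthSet(differential_genes=diffs)
    return (
        WindowedSignal(genome, width, vt),
        WindowedSignal(genome, width, ve),
        truth,
    )
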