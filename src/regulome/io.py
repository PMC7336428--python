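"""Readers and writers for the plain-text formats the pipeline touches.

BED and bedGraph are consumed verbatim (they are already 0-based half-open);
GFF3 (1-based inclusive) is converted to the internal convention here and
nowhere else. FASTA goes through Biopython.
"""

from __future__ import annotations

import os
from collections import defaultdict

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import numpy as np

from .model import GenomeModel, GenomicInterval, GeneModel, SegmentSet, WindowedSignal

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff_genes",
    "read_signal",
    "write_signal",
    "read_fasta",
    "write_fasta",
    "write_segments",
]


class ParseError(ValueError):
    pass


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals (coordinates verbatim)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from e
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return out


def write_bed(intervals, path) -> None:
    """Write intervals as BED; emits 6 columns when any name/score/strand set."""
    six = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                score = "0" if iv.score is None else format_score(iv.score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def format_score(x: float) -> str:
    """Render a score to 6 significant digits without trailing exponent noise."""
    return format(float(x), ".6g")


def write_segments(segset: SegmentSet, path) -> None:
    """BED6 with name=sign, score=mean standardized signal (6 digits)."""
    with open(path, "w") as fh:
        for s in segset:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.sign}\t{format_score(s.score)}\t.\n"
            )


# --- GFF3 -------------------------------------------------------------------

def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff_genes(path) -> list[GeneModel]:
    """Read gene models from GFF3, keeping one primary transcript per gene.

    The primary transcript is the mRNA with the longest total CDS (ties by
    lexicographically smallest mRNA id). GFF's 1-based inclusive coordinates
    become 0-based half-open; duplicated UTR records are collapsed.
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f
            start, end = int(start1) - 1, int(end1)
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "interval": GenomicInterval(chrom, start, end, strand),
                    "mrnas": [],
                }
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid is None or parent is None:
                    raise ParseError(f"{path}:{lineno}: mRNA without ID/Parent")
                mrnas[mid] = {
                    "gene": parent,
                    "exons": [],
                    "five": [],
                    "three": [],
                    "cds_bp": 0,
                }
                genes.setdefault(parent, {"interval": None, "mrnas": []})
                genes[parent]["mrnas"].append(mid)
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a.get("Parent")
                if parent not in mrnas:
                    continue
                rec = mrnas[parent]
                iv = (chrom, start, end, strand)
                if ftype == "exon":
                    rec["exons"].append(iv)
                elif ftype == "CDS":
                    rec["cds_bp"] += end - start
                elif ftype == "five_prime_UTR":
                    rec["five"].append(iv)
                else:
                    rec["three"].append(iv)

    out = []
    for gid in sorted(genes):
        g = genes[gid]
        if g["interval"] is None or not g["mrnas"]:
            continue
        primary = min(g["mrnas"], key=lambda m: (-mrnas[m]["cds_bp"], m))
        rec = mrnas[primary]

        def mk(tuples):
            # collapse duplicated records (e.g. repeated 5' UTR lines)
            seen = sorted(set(tuples))
            return tuple(GenomicInterval(c, s, e, st) for c, s, e, st in seen)

        gene_iv = g["interval"]
        exons = mk(rec["exons"])
        for child in exons + mk(rec["five"]) + mk(rec["three"]):
            if child.start < gene_iv.start or child.end > gene_iv.end:
                raise ParseError(f"gene {gid}: child feature outside gene span")
        out.append(
            GeneModel(gid, gene_iv, exons, mk(rec["five"]), mk(rec["three"]))
        )
    return out


def write_gff_genes(genes, path) -> None:
    """Write gene models as GFF3 (one mRNA per gene), converting back to
    1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tregulome\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.id}\n"
            )
            mid = f"{g.id}.t1"
            fh.write(
                f"{iv.chrom}\tregulome\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={mid};Parent={g.id}\n"
            )
            for ftype, children in (
                ("exon", g.exons),
                ("five_prime_UTR", g.five_utr),
                ("three_prime_UTR", g.three_utr),
            ):
                for c in children:
                    fh.write(
                        f"{c.chrom}\tregulome\t{ftype}\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t.\tParent={mid}\n"
                    )
            # CDS = exon span minus terminal UTRs; emitted so the primary
            # transcript rule has something to measure on re-read
            utr = {(u.start, u.end) for u in g.five_utr + g.three_utr}
            for c in g.exons:
                s, e = c.start, c.end
                for us, ue in sorted(utr):
                    if us <= s < ue:
                        s = ue
                    if us < e <= ue:
                        e = us
                if e > s:
                    fh.write(
                        f"{c.chrom}\tregulome\tCDS\t{s + 1}\t{e}\t.\t{c.strand}\t0\tParent={mid}\n"
                    )


# --- bedGraph ---------------------------------------------------------------

def write_signal(signal: WindowedSignal, path) -> None:
    """Write a WindowedSignal as bedGraph, windows in genomic order."""
    w = signal.width
    with open(path, "w") as fh:
        for chrom, length in signal.genome.chromosomes:
            v = signal.values[chrom]
            for i, x in enumerate(v):
                end = min((i + 1) * w, length)
                fh.write(f"{chrom}\t{i * w}\t{end}\t{format_score(x)}\n")


def read_signal(path, genome: GenomeModel | None = None) -> WindowedSignal:
    """Read a bedGraph produced by :func:`write_signal`.

    The window width is inferred from the records; varying widths (other than
    a final partial window per chromosome) or overlapping intervals raise.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            per_chrom[chrom].append((int(s), int(e), float(v)))

    widths = set()
    for chrom, rows in per_chrom.items():
        rows.sort()
        for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise ParseError(f"{path}: overlapping bedGraph intervals on {chrom}")
        widths.update(e - s for s, e, _ in rows[:-1])
        widths.add(rows[0][1] - rows[0][0])
    if len(widths) > 1:
        raise ParseError(f"{path}: inconsistent window widths {sorted(widths)}")
    width = widths.pop()

    if genome is None:
        genome = GenomeModel(
            tuple((c, per_chrom[c][-1][1]) for c in sorted(per_chrom))
        )
    values = {}
    for chrom, length in genome.chromosomes:
        n = -(-length // width)
        v = np.zeros(n)
        for s, e, x in per_chrom.get(chrom, []):
            if s % width:
                raise ParseError(f"{path}: window start {s} not aligned to width {width}")
            v[s // width] = x
        values[chrom] = v
    return WindowedSignal(genome, width, values)


# --- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased. Empty records are an error."""
    out = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, os.fspath(path), "fasta")
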