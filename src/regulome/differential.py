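"""Tissue-differential promoter accessibility coupled to expression.

Per gene, DNS is compared between two tissues (tassel minus ear) over the
25-bp windows covering the 500 bp upstream of the TSS. The per-gene delta
is the signed per-window difference of maximal absolute value; deltas > 1
(< -1) call the promoter differentially accessible in tassel (ear). Genes
are filtered on RNA-seq read coverage (> 100 in either tissue) and a |1.5|
TPM fold change separates expression classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GeneModel, WindowedSignal

__all__ = [
    "promoter_delta",
    "direction_of",
    "expression_filter",
    "expression_class",
    "classify",
    "DifferentialCall",
    "call_differential",
    "rank_by_delta",
]

DELTA_THRESHOLD = 1.0
FC_CUTOFF = 1.5
COVERAGE_MIN = 100

FINAL_CLASSES = {
    ("tassel", "up_tassel"): "accessible_up_tassel",
    ("ear", "up_ear"): "accessible_up_ear",
    ("tassel", "up_ear"): "accessible_tassel_up_ear",
    ("ear", "up_tassel"): "accessible_ear_up_tassel",
}


def promoter_delta(dns_t: WindowedSignal, dns_e: WindowedSignal, gene: GeneModel,
                   length: int = 500, aggregate: str = "extremum") -> float:
    """Signed differential accessibility over the 500-bp promoter.

    Computes per-window differences d_i = tassel - ear over the windows
    covering [TSS - length, TSS) (strand-aware), truncated to the
    chromosome. ``aggregate``: 'extremum' (default; the d_i of maximal
    absolute value, signed), 'mean' or 'sum'.
    """
    if not dns_t.compatible(dns_e):
        raise ValueError("tracks have mismatched genome or width")
    width = dns_t.width
    chrom = gene.interval.chrom
    L = dns_t.genome.length(chrom)
    tss = gene.tss
    if gene.strand != "-":
        lo, hi = tss - length, tss
    else:
        lo, hi = tss + 1, tss + 1 + length
    lo, hi = max(0, lo), min(L, hi)
    if hi <= lo:
        raise ValueError(f"gene {gene.id}: promoter entirely off chromosome")
    i0, i1 = lo // width, -(-hi // width)
    d = dns_t.values[chrom][i0:i1] - dns_e.values[chrom][i0:i1]
    if aggregate == "extremum":
        return float(d[np.argmax(np.abs(d))])
    if aggregate == "mean":
        return float(d.mean())
    if aggregate == "sum":
        return float(d.sum())
    raise ValueError(f"unknown aggregate {aggregate!r}")


def direction_of(delta: float, threshold: float = DELTA_THRESHOLD) -> str:
    if delta > threshold:
        return "tassel"
    if delta < -threshold:
        return "ear"
    return "none"


def expression_filter(coverage_t: float, coverage_e: float,
                      minimum: float = COVERAGE_MIN) -> bool:
    """Keep a gene when RNA-seq read coverage exceeds ``minimum`` in either tissue."""
    return max(coverage_t, coverage_e) > minimum


def expression_class(tpm_t: float, tpm_e: float, fc: float = FC_CUTOFF,
                     pseudocount: float = 1.0) -> str:
    """Classify expression change by pseudocounted TPM ratio at the |fc| cutoff."""
    r = (tpm_t + pseudocount) / (tpm_e + pseudocount)
    if r >= fc:
        return "up_tassel"
    if r <= 1 / fc:
        return "up_ear"
    return "unchanged"


def classify(direction: str, expr_class: str) -> str:
    """Five-class label from accessibility direction x expression class."""
    if direction == "none":
        raise ValueError("non-differential genes are excluded before classification")
    if expr_class == "unchanged":
        return "accessible_change_expression_unchanged"
    return FINAL_CLASSES[(direction, expr_class)]


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    delta: float
    direction: str
    expr_t: float
    expr_e: float
    fold_change: float
    expr_class: str
    final_class: str | None


def call_differential(dns_t: WindowedSignal, dns_e: WindowedSignal, genes,
                      coverage: dict[str, tuple[float, float]],
                      tpm: dict[str, tuple[float, float]],
                      length: int = 500, threshold: float = DELTA_THRESHOLD,
                      fc: float = FC_CUTOFF) -> list[DifferentialCall]:
    """Run the full differential-promoter pipeline over a gene set.

    ``coverage`` and ``tpm`` map gene id to (tassel, ear) values. Genes
    failing the coverage filter are dropped; all others get a call (with
    direction 'none' when the delta does not clear the threshold).
    """
    calls = []
    for g in genes:
        cov_t, cov_e = coverage[g.id]
        if not expression_filter(cov_t, cov_e):
            continue
        delta = promoter_delta(dns_t, dns_e, g, length)
        direction = direction_of(delta, threshold)
        tpm_t, tpm_e = tpm[g.id]
        ec = expression_class(tpm_t, tpm_e, fc)
        final = classify(direction, ec) if direction != "none" else None
        fold = (tpm_t + 1) / (tpm_e + 1)
        calls.append(DifferentialCall(g.id, delta, direction, tpm_t, tpm_e, fold, ec, final))
    return calls


def rank_by_delta(calls) -> pd.DataFrame:
    """Differential calls ordered by decreasing |delta| within direction.

    Ties are broken by gene id for determinism; non-differential calls are
    excluded.
    """
    rows = [
        {
            "gene_id": c.gene_id, "delta": c.delta, "direction": c.direction,
            "expr_t": c.expr_t, "expr_e": c.expr_e, "fold_change": c.fold_change,
            "expr_class": c.expr_class, "final_class": c.final_class,
        }
        for c in calls if c.direction != "none"
    ]
    df = pd.DataFrame(rows, columns=[
        "gene_id", "delta", "direction", "expr_t", "expr_e",
        "fold_change", "expr_class", "final_class",
    ])
    if len(df):
        df["_abs"] = df["delta"].abs()
        df = (
            df.sort_values(["direction", "_abs", "gene_id"],
                           ascending=[True, False, True])
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
    return df
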