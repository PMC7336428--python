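"""Functional-region GWAS marker subsetting and the lambda statistic.

Restricting a marker panel to functional (e.g. MNase-hypersensitive)
regions shrinks the multiple-testing burden; re-adjusting p-values on the
subset can promote markers past an FDR threshold. The lambda statistic
quantifies this: the ratio of the 99th percentiles of -log10 FDR-adjusted
p-values, reduced subset over genome-wide. lambda = 1 means no change; its
significance is judged against random same-size marker subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as ivt

__all__ = [
    "subset_markers",
    "bh_adjust",
    "lambda_stat",
    "LambdaResult",
    "lambda_null",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    For sorted p_(1..m), adj_(i) = min_{j >= i} m p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def subset_markers(markers: pd.DataFrame, regions) -> pd.DataFrame:
    """Markers whose position falls inside any region; subset-re-adjusted FDR.

    ``markers`` has columns (id, chrom, pos, p); positions are 0-based and
    region membership is half-open (a marker at a region's start is in, at
    its end is out). Raw p-values carry over; ``p_adj`` is recomputed by BH
    on the subset.
    """
    merged = {c: ivt.merge(a) for c, a in ivt.by_chrom(regions).items()}
    keep = [
        ivt.point_in_any(row.chrom, int(row.pos), merged)
        for row in markers.itertuples()
    ]
    sub = markers.loc[keep].copy().reset_index(drop=True)
    if len(sub):
        sub["p_adj"] = bh_adjust(sub["p"].to_numpy())
    else:
        sub["p_adj"] = []
    return sub


def lambda_stat(reduced_adj, genomewide_adj, q: float = 0.99) -> float:
    """Ratio of q-th percentiles of -log10 FDR-adjusted p-values.

    Percentiles use the linear-interpolation (type 7) quantile. All adjusted
    p-values must lie in (0, 1]; a zero denominator (every genome-wide
    adjusted p equal to 1) is an error.
    """
    red = np.asarray(reduced_adj, dtype=float)
    gw = np.asarray(genomewide_adj, dtype=float)
    if len(red) == 0 or len(gw) == 0:
        raise ValueError("empty p-value vector")
    for v in (red, gw):
        if np.any(v <= 0) or np.any(v > 1):
            raise ValueError("adjusted p-values must lie in (0, 1]")
    num = np.quantile(-np.log10(red), q, method="linear")
    den = np.quantile(-np.log10(gw), q, method="linear")
    if den == 0:
        raise ValueError("degenerate genome-wide distribution (all adjusted p = 1)")
    return float(num / den)


@dataclass(frozen=True)
class LambdaResult:
    lambda_obs: float
    null_mean: float
    null_sd: float
    z: float | None
    n_null: int


def lambda_null(markers: pd.DataFrame, subset_size: int, n: int = 1000,
                seed: int = 0, observed_lambda: float | None = None,
                q: float = 0.99) -> LambdaResult:
    """Null distribution of lambda over random same-size marker subsets.

    Each replicate draws ``subset_size`` markers uniformly without
    replacement (markers canonically sorted by id first, so input order is
    immaterial), BH-adjusts the subset, and computes lambda against the
    genome-wide adjustment of all markers. Returns the observed lambda (if
    given), the null mean/sd and the z-score; z is None when n = 1.
    """
    if subset_size > len(markers):
        raise ValueError("subset size exceeds marker count")
    if n < 1:
        raise ValueError("need at least one null replicate")
    markers = markers.sort_values("id", kind="stable").reset_index(drop=True)
    p = markers["p"].to_numpy()
    gw_adj = bh_adjust(p)
    rng = np.random.default_rng(seed)
    lam = np.empty(n)
    for k in range(n):
        idx = rng.choice(len(p), size=subset_size, replace=False)
        lam[k] = lambda_stat(bh_adjust(p[idx]), gw_adj, q)
    null_mean = float(lam.mean())
    null_sd = float(lam.std(ddof=1)) if n > 1 else float("nan")
    z = None
    if observed_lambda is not None and n > 1 and null_sd > 0:
        z = (observed_lambda - null_mean) / null_sd
    return LambdaResult(
        lambda_obs=float("nan") if observed_lambda is None else float(observed_lambda),
        null_mean=null_mean, null_sd=null_sd, z=z, n_null=n,
    )
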