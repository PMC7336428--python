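# regulome

Analysis of differential MNase-seq chromatin profiling for regulatory-landscape
mapping, built around the maize inflorescence-primordia assay design: paired
light and heavy micrococcal-nuclease digests, differential sensitivity tracks,
hypersensitive-region segmentation, TF-footprint calling, genomic-context
statistics, tissue-differential promoter accessibility coupled to expression,
lncRNA annotation and co-expression, and functional-region GWAS statistics.
Every stage runs on seed-controlled synthetic data with planted ground truth,
so the whole pipeline is testable without sequencing downloads.

## The method

**DNS track.** Micrococcal nuclease digests nucleosome-free DNA preferentially.
Coverage of sequenced fragments is computed as mean per-base depth in 25-bp
windows, scaled to reads per million (RPM), and the differential nuclease
sensitivity is

```
DNS = light RPM − heavy RPM
```

per window: positive values mark accessible chromatin, negative values
MNase-resistant (nucleosome-occupied) chromatin. The **LCS** track is light
coverage restricted to sub-nucleosomal fragments (< 131 bp), a proxy for
TF-scale particles.

**Segmentation.** Tracks are z-standardized genome-wide and segments are
maximal runs of windows beyond a biological cutoff **bc** (z ≥ bc
hypersensitive, z ≤ −bc resistant), bc 0.5 lenient … 2.0 default … 4.0
stringent. Replicates are reconciled by greedy nearest-midpoint matching
within 300 bp.

**Footprints.** Centers of small light-digest fragments are counted in 21-bp
windows assigned to central 5-bp blocks (5-bp step); positive segments of the
standardized track at bc 4.0 give ~20-bp footprint calls.

**Differential promoters.** Per gene, the signed extremum of per-window
(tassel − ear) DNS differences over the 500 bp upstream of the TSS; |Δ| > 1
calls the promoter differentially accessible, combined with an RNA-seq
coverage filter (> 100) and a |1.5| TPM fold-change classification into five
gene classes.

**lncRNAs.** A transcript survives the filter cascade when it is ≥ 200 nt, its
longest ORF is ≤ 100 aa, it carries no protein-domain / coding-potential /
structural-RNA flag, hosts < 20 distinct small-RNA reads (18–34 nt), and sums
to ≥ 10 TPM across stages. Survivors are positionally classified
(antisense / exonic / intronic / exon–intron / intergenic ≤ 2 kb, ≤ 10 kb,
> 10 kb), scored for stage specificity with the normalized Shannon entropy
SH = 1 − H/log2(n), and paired with their closest gene when the biweight
midcorrelation of log2(TPM+1) profiles exceeds |0.8|.

**GWAS λ.** Restricting a marker panel to functional regions and re-adjusting
p-values (Benjamini–Hochberg) is summarized by

```
λ = Q99(−log10 reduced FDR-adjusted p) / Q99(−log10 genome-wide FDR-adjusted p)
```

λ = 1 means no change in the top percentile; significance is judged against a
null of random same-size marker subsets.

## Worked example

`examples/01_signal_and_segmentation.py` simulates a 2 Mb genome with 200
planted accessible sites and a paired digest of 2 × 200,000 fragments, builds
the DNS track and calls HS regions:

```
called 203 HS segments at bc 2.0
recovered 200/200 planted accessible sites
accessible fraction: 2.93% of the genome
```

All planted sites are recovered and the called accessible fraction matches
the planted 3% of the genome. `examples/06_gwas_lambda.py` plants association
signal inside those HS regions and measures the λ statistic:

```
50000 markers, 409 carry planted signal
subset inside HS regions: 1433 markers
lambda = 25.01 (null 1.18 +/- 0.71, z = 33.4)
```

The functional subset's 99th percentile of −log10 adjusted p-values is 25×
the genome-wide one, dozens of null standard deviations away — the planted
enrichment is recovered. The other examples cover footprints, genomic
context, differential promoters and lncRNA co-expression.

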