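# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of the package. Coordinates are 0-based half-open everywhere
internally; GFF3 (1-based inclusive) is converted at the I/O boundary.

## Signal model

Window coverage is the mean per-base fragment depth over a window's bases
(default width 25 bp); a fragment contributes to every base it covers, so
fragments crossing window boundaries contribute proportionally, and the final
partial window of a chromosome is averaged over its true width. RPM scaling
divides by the total fragment count of the *parent* library — also for
size-filtered tracks such as LCS — so all-fragment and small-fragment tracks
share one scale. The counting unit is the fragment, not the read pair.

The DNS track is the per-window difference light − heavy of RPM tracks.
The small/large fragment partition uses the sub-nucleosomal boundary
length < 131 bp.

Genome-scale summaries use 1 Mb sliding windows at 100 kb steps; the `mean`
statistic averages the member 25-bp values, and `positive_z` averages only
the positive members (0 where none are positive) as an accessibility-weighted
summary — the definition of the positive-signal summary was an open design
choice here.

## Segmentation

The biological cutoff bc is interpreted as a z-score threshold on the
genome-standardized track: standardization moments are computed over **all**
windows of the genome (zeros included), with a robust MAD-based alternative
behind a flag. Positive segments are maximal runs of windows with z ≥ bc;
runs separated by at most `max_gap_windows` sub-threshold windows merge, and
the segment score is the mean z over member *and* gap windows. This is a
deliberate, fully specified stand-in for published changepoint-based
segmenters whose internals are out of scope; it reproduces the bc 0.5–3.0
stringency semantics and is exactly testable against run enumeration. One
consequence: with gap merging at lenient cutoffs a segment's score can cross
zero, so segment sign is defined by the threshold side, not the score sign.

Replicate reconciliation retains equal-sign segment pairs whose midpoints lie
within 300 bp, pairing greedily by nearest midpoint (each segment used once)
and emitting the union span; the criterion distance is the only constraint
stated by the assay design, the greedy rule is ours.

## Footprints

Centers of small fragments ((start + end) // 2, floor for even lengths) are
counted in 21-bp windows assigned to the central 5-bp block at a 5-bp step;
each center therefore lands in 4 or 5 blocks. Blocks truncated by the
chromosome end keep raw counts (no edge scaling). The blocked counts are
standardized directly (no pre-normalization) and positive segments at bc 4.0,
converted back from block to bp coordinates, are the footprint calls.

## Genomic context

Exclusive feature assignment uses the precedence
five_utr > three_utr > exon > intron > proximal_promoter > upstream_1kb >
upstream_1to2kb > downstream_1kb > intergenic, strand-aware, with the
proximal promoter spanning 1 kb upstream to 200 bp downstream of the TSS.
Because the upstream_1kb span is a subset of the promoter span, that label is
unreachable in exclusive assignment; it remains meaningful in the
non-exclusive density tally, which counts a midpoint toward every feature
space containing it, normalized per 10 kb of feature space (features with no
genomic space report missing, not zero).

Intergenic distances are measured to the nearest gene boundary (not TSS), 0
inside a gene; the null set scores the midpoints of inter-gene gaps the same
way, and medians are compared with Welch's unequal-variance t-test.

Permutation enrichment circularly shifts all query regions of a chromosome by
one uniform offset per permutation (wrap-around), preserving inter-region
spacing, count and total bp exactly. The statistic is midpoint-in-region
counts by default, bp overlap by flag; the empirical p-value uses the
(1 + #{null ≥ obs})/(n + 1) estimator, which never returns zero. With small
discrete statistics this estimator is conservative (ties count against
rejection), so null rejection rates sit at or slightly below the nominal
level.

ChIP concordance: `summit300` keeps peak pairs with summits (midpoints)
within 300 bp and emits the summit midpoint ± half the mean of the two peak
spans ("half the original span" is ambiguous for unequal spans; the mean was
chosen); `reciprocal50` keeps pairs whose overlap reaches 50% of the smaller
peak and emits the union. Co-binding uses the 500-bp midpoint rule. Motif
modules join motif pairs whose end-to-start gap is ≤ 50 bp (0 when
overlapping). Term enrichment is the upper-tail hypergeometric test with
Benjamini–Hochberg correction across terms.

## Profiles

Window-valued signals are sampled at base resolution (each base takes its
window's value). TSS metaplots average raw values per offset over genes,
strand-flipped for minus-strand genes, dropping out-of-chromosome offsets;
means rather than sums keep differently sized groups comparable, and no
per-gene normalization is applied before averaging (an open choice,
documented). Metagene profiles rescale the body to 100 bins and append
fixed-bp flanks. Methylation profiles bin per-cytosine ratios per context
(CG/CHG/CHH); bins without cytosines are missing, not zero. Expression
tertiles sort by TPM with ties broken by gene id; remainders go to the
lowest groups first.

## Differential promoters

The per-gene delta is computed over the 25-bp windows covering
[TSS − 500, TSS) (strand-aware, truncated at chromosome edges) as the signed
per-window difference of maximal absolute value. The extremum was chosen as
the aggregation because the differential-accessibility definition is
per-window (a change beyond ±1 in any window) while ranking needs one signed
number per gene; mean and sum aggregations are available by flag. The
coverage filter keeps genes with > 100 RNA-seq read coverage in either
tissue (the stricter per-tissue reading is ambiguous); the fold-change
classification uses pseudocount 1 on TPMs to handle zeros: ratio ≥ 1.5 up in
tissue A, ≤ 1/1.5 up in tissue B, else unchanged. Swapping tissue inputs
negates every delta and swaps every class exactly.

## lncRNA cascade and co-expression

Filters apply in the fixed order length < 200 nt, longest ORF > 100 aa,
domain flag, coding-potential flag, structural-RNA flag, ≥ 20 distinct hosted
small RNAs, total TPM < 10; each dropped transcript is attributed to its
first failing filter, and the retained set is order-independent because the
filters are conjunctive. The three homology/coding flags are pluggable
boolean inputs — computing them needs external databases (Pfam/CPC/Rfam
class scans), which is out of scope. ORF scanning covers the three forward
frames only (assembled transcripts are oriented), requires an in-frame stop,
and counts the initial Met but not the stop. Small-RNA hosting counts
distinct 18–34-nt read sequences matching exactly in either orientation
(mismatch-tolerant matching is not implemented; the default in the original
mapping tool is also 0 mismatches).

Stage specificity is SH = 1 − H/log2(n) on the TPM proportions: 1 for
one-hot, 0 for uniform; SH ≥ 0.6 reads as stage-specific and SH ≤ 0.2 as
broad. The biweight midcorrelation uses Tukey biweights with u = (x −
median)/(9·MAD), unscaled MAD, weights (1 − u²)² for |u| < 1; zero MAD falls
back to Pearson with a warning. Expression is log2(TPM + 1)-transformed
before correlation — a model-free stand-in for variance-stabilizing
transforms that require a fitted dispersion model. Pairing links each
lncRNA of a pairing class (intronic; intergenic ≤ 2 kb, ≤ 10 kb, > 10 kb) to
its single closest coding gene (all-in-bin pairing is a flag), keeping
|bicor| > 0.8. Modules cluster the retained pairs by complete linkage on
1 − bicor of pair profiles — defined here as the mean of the z-scored log
profiles of the lncRNA and its gene — with the tree cut at height 0.25.

## GWAS λ

Benjamini–Hochberg adjustment is the step-up rule adj(i) = min over j ≥ i of
m·p(j)/j, capped at 1, returned in input order. λ is the ratio of 99th
percentiles of −log10 adjusted p-values, reduced subset over genome-wide,
with the linear-interpolation (type 7) quantile — the quantile rule is not
dictated by the definition and matters at small n; λ itself is invariant to
the log base. The observed λ's denominator is always the genome-wide
adjustment of all markers. The null redraws uniform subsets of the observed
subset's size without replacement (markers canonically sorted by id first so
input order is immaterial), re-adjusts each, and reports mean, SD and the
z-score of the observed λ; with a single replicate the SD and z are
undefined and reported missing. The null λ distribution is right-skewed, so
single-draw z-scores occasionally exceed 3 even under the null; calibration
summaries should use several draws (the acceptance script reports a median
over 11).

## Synthetic data: what it emulates, and what it does not

All generators take an explicit seed, use one `numpy` Generator per call and
no global state, and can serialize their ground truth to JSON so recovery
tests run from files alone.

Defaults define the study conditions: a 2 × 1 Mb genome; 60 genes (1.5–4 kb,
1–5 exons, terminal UTRs, uniform strands, ≥ 2 kb apart); 40 intergenic TEs;
200 planted 300-bp HS sites of which a quarter sit immediately upstream of a
gene TSS (mirroring the promoter-biased accessibility of the assay) and 50
carry a central TF footprint; 2 × 10⁵ fragments per digest at enrichment 8.

Fragment model: background centers are uniform with mononucleosomal lengths
Normal(147, 10) clipped to [100, 220]. In the light digest, a fragment's
center falls in HS space with probability min(1, enrichment × hs_fraction)
(background fills the complement), and in-HS fragments draw sub-nucleosomal
lengths Normal(80, 15) clipped to [30, 130] with probability 1 − 1/enrichment
— so enrichment 1 reduces exactly to background, and both the center-density
and the small-fragment excess at accessible sites scale with one knob. Half
of the small in-HS fragments at footprint-bearing sites cluster on the
footprint (SD 4 bp). The heavy digest is pure background. The model has no
sequence bias, no GC or mappability structure, no chimeric fragments and no
replicate batch effects; passing recovery tests therefore demonstrates the
statistical machinery, not robustness to those artefacts.

Differential promoter tracks: both tissues share a unit-SD per-window
baseline plus independent Normal(0, 0.15) noise; planted genes get +3 (three
baseline SDs) added to the tissue of their planted direction over the
promoter windows. The offset clears the ±1 delta threshold with margin while
zero-offset genes stay far below it.

Expression: unpaired transcripts are iid log-normal per stage
(exp(Normal(1.5, 1))); planted pairs share a log-normal latent profile with
noise calibrated to the target correlation and are redrawn (deterministically,
bounded) until the realized TPM-scale Pearson r reaches the target magnitude
and sign. Transcripts are built on an A-free backbone so the only ATG and
stop codons are the planted ones, making the designed longest-ORF length
exact; hosted small RNAs are distinct 21-mers extracted from the transcript,
plus decoy reads containing A that can match nothing. Stage TPM vectors are
dyadic multinomial splits so designed TPM sums are exact in floating point.

Markers are uniform over the genome with p ~ Uniform(0, 1]; a fraction
pi_signal (default 0.3) of markers inside HS regions draw p ~ Beta(0.2, 1).
Methylation plants cytosines at 0.05/bp with CG/CHG high distally (0.8) and
depressed in gene bodies (0.15), CHH at 0.05 background plus a +0.5 island in
the 200 bp immediately upstream of each TSS, Normal(0, 0.05) noise, clipped
to [0, 1].

## Problem sizes

Tests and the acceptance script run on the 2 Mb default genome with
2 × 10⁵ fragments per digest, 5 × 10⁴ markers, 200-replicate permutation and
subset nulls, and 200 calibration datasets — sizes at which every planted
effect is comfortably detectable and the full suite completes in well under a
minute per stage on one CPU.

## Known limitations

- The bc-threshold segmentation approximates, but is not, the published
  changepoint segmenter; absolute segment counts at a given bc are not
  comparable across the two.
- Flags for coding potential and domain/structural homology are inputs, not
  computed; the cascade's attribution therefore depends on upstream tools.
- The permutation p-value is conservative for small discrete statistics (see
  above).
- `high_confidence` greedy matching is optimal for the nearest-pair
  criterion but is not a maximum-cardinality matching; pathological midpoint
  arrangements can pair fewer segments than the optimum.
- Real-data headline figures of the assay (genome-wide accessible fractions,
  absolute region counts) depend on genome size, depth and external tool
  versions and are not reproduced at desk scale; the package's claims are
  the property-level guarantees its tests compute.
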