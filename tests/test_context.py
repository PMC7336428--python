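import math

import numpy as np
import pytest

from regulome import context as ctx
from regulome.model import AnnotationSet, GeneModel, GenomeModel, GenomicInterval, SegmentSet, Segment


@pytest.fixture
def toy_genome():
    return GenomeModel((("chr1", 100_000),))


@pytest.fixture
def toy_annotation(toy_genome):
    """Three genes: plus-strand with intron, minus-strand, single-exon."""
    g1 = GeneModel(
        "gA",
        GenomicInterval("chr1", 10_000, 14_000, "+"),
        exons=(GenomicInterval("chr1", 10_000, 11_000, "+"),
               GenomicInterval("chr1", 12_000, 14_000, "+")),
        five_utr=(GenomicInterval("chr1", 10_000, 10_200, "+"),),
        three_utr=(GenomicInterval("chr1", 13_800, 14_000, "+"),),
    )
    g2 = GeneModel(
        "gB",
        GenomicInterval("chr1", 30_000, 33_000, "-"),
        exons=(GenomicInterval("chr1", 30_000, 33_000, "-"),),
    )
    g3 = GeneModel(
        "gC",
        GenomicInterval("chr1", 60_000, 62_000, "+"),
        exons=(GenomicInterval("chr1", 60_000, 62_000, "+"),),
    )
    return AnnotationSet(genes=[g1, g2, g3])


class TestAssignFeature:
    @pytest.mark.parametrize("pos,expect", [
        (9_500, "proximal_promoter"),    # 500 bp upstream of gA's TSS
        (10_100, "five_utr"),
        (11_300, "intron"),              # 300 bp into the intron
        (12_500, "exon"),
        (13_900, "three_utr"),
        (14_500, "downstream_1kb"),
        (8_500, "upstream_1to2kb"),
        (50_000, "intergenic"),          # > 2 kb from any gene or flank
        (33_200, "proximal_promoter"),   # minus-strand gB: upstream is rightward
        (29_500, "downstream_1kb"),      # minus-strand gB: downstream is leftward
    ])
    def test_labels(self, toy_annotation, toy_genome, pos, expect):
        assert ctx.assign_feature("chr1", pos, toy_annotation, toy_genome) == expect

    def test_out_of_genome_rejected(self, toy_annotation, toy_genome):
        with pytest.raises(ValueError):
            ctx.assign_feature("chr1", 100_000, toy_annotation, toy_genome)

    def test_total_every_point_labelled(self, toy_annotation, toy_genome):
        rng = np.random.default_rng(0)
        spaces = ctx._merged_spaces(toy_annotation, toy_genome)
        for pos in rng.integers(0, 100_000, size=300):
            lab = ctx.assign_feature("chr1", int(pos), toy_annotation, toy_genome, _spaces=spaces)
            assert lab in ctx.FEATURE_LABELS


class TestFeatureDensity:
    def test_hand_tally(self, toy_annotation, toy_genome):
        # three midpoints in exon space (5000 bp total exon space for gA+gB+gC)
        mids = [GenomicInterval("chr1", m, m + 1) for m in (10_500, 12_500, 30_500)]
        table = ctx.feature_density(mids, toy_annotation, toy_genome)
        row = table.set_index("feature").loc["exon"]
        assert row["midpoints"] == 3
        assert row["space_bp"] == 8_000  # 3000 + 3000 + 2000
        assert row["per_10kb"] == pytest.approx(3 / 0.8)

    def test_density_is_superset_of_exclusive_labels(self, toy_annotation, toy_genome):
        # a 5' UTR midpoint counts in both five_utr and exon spaces
        mids = [GenomicInterval("chr1", 10_100, 10_101)]
        table = ctx.feature_density(mids, toy_annotation, toy_genome).set_index("feature")
        assert table.loc["five_utr", "midpoints"] == 1
        assert table.loc["exon", "midpoints"] == 1

    def test_empty_space_is_missing(self, toy_genome):
        ann = AnnotationSet(genes=[GeneModel(
            "g", GenomicInterval("chr1", 1000, 2000, "+"),
            exons=(GenomicInterval("chr1", 1000, 2000, "+"),),
        )])
        table = ctx.feature_density([], ann, toy_genome).set_index("feature")
        assert math.isnan(table.loc["intron", "per_10kb"])


class TestDistances:
    def test_hand_examples(self):
        genes = [
            GeneModel("a", GenomicInterval("chr1", 1000, 2000, "+"),
                      exons=(GenomicInterval("chr1", 1000, 2000, "+"),)),
            GeneModel("b", GenomicInterval("chr1", 10_000, 12_000, "+"),
                      exons=(GenomicInterval("chr1", 10_000, 12_000, "+"),)),
        ]
        d = ctx.nearest_gene_distance([("chr1", 5000)], genes)
        assert d[0] == 3000
        null = ctx.gap_null(genes)
        assert null.tolist() == [4000.0]  # gap midpoint 6000

    def test_inside_gene_is_zero(self):
        genes = [GeneModel("a", GenomicInterval("chr1", 1000, 2000, "+"),
                           exons=(GenomicInterval("chr1", 1000, 2000, "+"),))]
        assert ctx.nearest_gene_distance([("chr1", 1500)], genes)[0] == 0

    def test_welch_identical_distributions(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = ctx.distance_test(x, x.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestPermutationEnrichment:
    def test_p_formula_matches_hand_count(self, toy_genome):
        """Recompute the null >= observed count with the same RNG stream."""
        query = [GenomicInterval("chr1", s, s + 100) for s in range(0, 5000, 500)]
        ref = [GenomicInterval("chr1", 0, 50_000)]
        n = 10
        res = ctx.permutation_enrichment(query, ref, toy_genome, n=n, seed=42)
        rng = np.random.default_rng(42)
        mids = np.array([iv.midpoint for iv in query])
        count = 0
        for _ in range(n):
            off = int(rng.integers(100_000))
            shifted = (mids + off) % 100_000
            stat = int(np.sum(shifted < 50_000))
            if stat >= res.observed:
                count += 1
        assert res.empirical_p == pytest.approx((1 + count) / (n + 1))

    def test_self_reference_is_maximal(self, toy_genome):
        query = [GenomicInterval("chr1", s, s + 1000) for s in range(0, 50_000, 5000)]
        res = ctx.permutation_enrichment(query, query, toy_genome, n=50, seed=1)
        assert res.observed == len(query)
        assert res.empirical_p <= 0.5

    def test_circular_shift_preserves_count_and_bp(self, toy_genome):
        query = [GenomicInterval("chr1", s, s + 123) for s in (10, 5000, 99_000)]
        res = ctx.permutation_enrichment(query, query, toy_genome, n=20, seed=0, statistic="bp")
        assert res.observed == 3 * 123  # self-overlap is total bp: shifts cannot beat it

    def test_nonpositive_n_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            ctx.permutation_enrichment([], [], toy_genome, n=0)

    def test_planted_te_enrichment(self, genome, annotation):
        """Query regions planted inside TE space are strongly enriched."""
        rng = np.random.default_rng(1)
        tes = annotation.tes
        query = []
        for te in (tes[i] for i in rng.choice(len(tes), 60)):
            m = te.midpoint
            query.append(GenomicInterval(te.chrom, max(0, m - 50), m + 50))
        res = ctx.permutation_enrichment(query, tes, genome, n=1000, seed=2)
        assert res.empirical_p <= 0.001


class TestChip:
    def test_summit_distance_rule(self):
        a = [GenomicInterval("chr1", 50, 150)]    # summit 100
        b = [GenomicInterval("chr1", 300, 400)]   # summit 350
        assert len(ctx.chip_concordance(a, b, "summit300")) == 1
        c = [GenomicInterval("chr1", 450, 550)]   # summit 500
        assert len(ctx.chip_concordance(a, c, "summit300")) == 0

    def test_reciprocal_overlap_rule(self):
        a = [GenomicInterval("chr1", 0, 100)]
        kept = ctx.chip_concordance(a, [GenomicInterval("chr1", 50, 150)], "reciprocal50")
        assert len(kept) == 1  # overlap 50 = 50% of the smaller peak
        dropped = ctx.chip_concordance(
            [GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 80, 300)], "reciprocal50"
        )
        assert len(dropped) == 0  # overlap 20 < 50% of 100

    def test_cobound_by_midpoint(self):
        p1 = [GenomicInterval("chr1", 0, 200)]     # midpoint 100
        p2 = [GenomicInterval("chr1", 400, 600)]   # midpoint 500
        assert len(ctx.cobound(p1, p2, 500)) == 1
        p3 = [GenomicInterval("chr1", 1000, 1400)]  # midpoint 1200
        assert len(ctx.cobound(p1, p3, 500)) == 0

    def test_overlap_fraction(self):
        peaks = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 200, 300),
            GenomicInterval("chr1", 500, 600),
            GenomicInterval("chr1", 800, 900),
        ]
        hs = [GenomicInterval("chr1", 50, 60), GenomicInterval("chr1", 250, 260)]
        assert ctx.overlap_with(peaks, hs) == pytest.approx(0.5)
        assert ctx.overlap_with(peaks, []) == 0.0


class TestMotifProximity:
    def test_hand_example(self):
        a = [GenomicInterval("chr1", 1000, 1006)]
        b = [GenomicInterval("chr1", 1030, 1036)]
        d, modules = ctx.motif_proximity(a, b, window=50)
        assert d[0] == 24
        assert len(modules) == 1
        m = modules.segments[0].interval
        assert (m.start, m.end) == (1000, 1036)

    def test_gap_beyond_window_gives_no_module(self):
        a = [GenomicInterval("chr1", 1000, 1006)]
        b = [GenomicInterval("chr1", 1066, 1072)]
        d, modules = ctx.motif_proximity(a, b, window=50)
        assert d[0] == 60 and len(modules) == 0

    def test_overlapping_motifs_distance_zero(self):
        a = [GenomicInterval("chr1", 1000, 1010)]
        b = [GenomicInterval("chr1", 1005, 1015)]
        d, _ = ctx.motif_proximity(a, b)
        assert d[0] == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(7)
        a = [GenomicInterval("chr1", int(s), int(s) + 8) for s in rng.integers(0, 5000, 30)]
        b = [GenomicInterval("chr1", int(s), int(s) + 8) for s in rng.integers(0, 5000, 30)]
        d, _ = ctx.motif_proximity(a, b)
        for i, x in enumerate(a):
            gaps = [
                max(0, max(x.start, y.start) - min(x.end, y.end)) for y in b
            ]
            assert d[i] == min(gaps)


class TestTermEnrichment:
    def test_brute_force_hypergeometric(self):
        universe = [f"g{i}" for i in range(100)]
        term_map = {"T": set(universe[:10])}
        selected = universe[:5] + universe[50:65]  # k=5 of K=10 in n=20
        out = ctx.term_enrichment(selected, universe, term_map)
        expect = sum(
            math.comb(10, j) * math.comb(90, 20 - j) / math.comb(100, 20)
            for j in range(5, 11)
        )
        assert out.loc[0, "p"] == pytest.approx(expect, rel=1e-12)

    def test_zero_hits_p_is_one(self):
        universe = [f"g{i}" for i in range(50)]
        out = ctx.term_enrichment(universe[:10], universe, {"T": set(universe[40:])})
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ctx.term_enrichment(["x"], ["a", "b"], {"T": {"a"}})

    def test_bh_applied_across_terms(self):
        universe = [f"g{i}" for i in range(100)]
        term_map = {
            "T1": set(universe[:10]),
            "T2": set(universe[10:30]),
            "T3": set(universe[30:35]),
        }
        out = ctx.term_enrichment(universe[:10], universe, term_map)
        assert (out["q"] >= out["p"] - 1e-12).all()
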