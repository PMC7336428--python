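import numpy as np
import pytest

from regulome import lncrna as lnc
from regulome.model import AnnotationSet, GeneModel, GenomicInterval
from regulome.simulate import default_transcript_design, simulate_expression, simulate_transcripts


class TestLongestOrf:
    @pytest.mark.parametrize("seq,expect", [
        ("ATGAAATAA", 2),                       # M-K-stop
        ("CCCCCCCCC", 0),                       # no ATG
        ("ATG" + "AAA" * 100 + "TAA", 101),
        ("ATGAAA", 0),                          # no in-frame stop
        ("CATGAAATAACC", 2),                    # frame 1
        ("ATGTAAATGAAAAAATAA", 3),              # longest of two ORFs in frame 0
    ])
    def test_hand_translations(self, seq, expect):
        assert lnc.longest_orf(seq) == expect

    def test_agrees_with_designed_transcripts(self):
        seqs, _, _, _ = simulate_transcripts(seed=3)
        design = default_transcript_design().set_index("id")
        for tid, seq in seqs.items():
            assert lnc.longest_orf(seq) == design.loc[tid, "orf_aa"]


class TestSmallRnaHosting:
    def test_duplicate_reads_count_once(self):
        seq = "A" * 10 + "CGTACGTACGTACGTACGTAC" + "A" * 10
        read = "CGTACGTACGTACGTACGTAC"
        assert lnc.smallrna_hosting(seq, [read, read]) == 1

    def test_length_bounds(self):
        seq = "ACGT" * 30
        assert lnc.smallrna_hosting(seq, ["ACGTACGTACGTACGTA"]) == 0   # 17 nt
        assert lnc.smallrna_hosting(seq, ["ACGTACGTACGTACGTAC"]) == 1  # 18 nt
        assert lnc.smallrna_hosting(seq, ["ACGT" * 8 + "AC"]) == 1     # 34 nt
        assert lnc.smallrna_hosting(seq, ["ACGT" * 8 + "ACG"]) == 0    # 35 nt

    def test_reverse_complement_matches(self):
        seq = "GGGGGCCCCCTTTTTAAAAAGGGGG"
        read = lnc.reverse_complement(seq[2:22])
        assert lnc.smallrna_hosting(seq, [read]) == 1


class TestFilterCascade:
    def test_boundary_record_retained(self):
        """ORF of exactly 100 aa, 19 small RNAs and sum TPM exactly 10 pass."""
        rec = lnc.TranscriptRecord(
            "t", "C" * 300, distinct_smallrna=19, tpm=np.array([10.0] + [0.0] * 7)
        )
        retained, _ = lnc.filter_cascade([rec])
        assert len(retained) == 1

    @pytest.mark.parametrize("kw,filt", [
        (dict(sequence="C" * 150), "min_length"),
        (dict(domain_hit=True), "domain_hit"),
        (dict(coding_potential=True), "coding_potential"),
        (dict(structural_rna=True), "structural_rna"),
        (dict(distinct_smallrna=20), "smallrna_host"),
        (dict(tpm=np.full(8, 1.0)), "min_expression"),
    ])
    def test_each_filter_triggers(self, kw, filt):
        base = dict(id="t", sequence="C" * 300, tpm=np.full(8, 5.0))
        base.update(kw)
        retained, tally = lnc.filter_cascade([lnc.TranscriptRecord(**base)])
        assert len(retained) == 0
        assert tally[filt] == 1

    def test_orf_over_100_aa_dropped(self):
        seq = "ATG" + "CCC" * 100 + "TAA" + "C" * 50
        rec = lnc.TranscriptRecord("t", seq, tpm=np.full(8, 5.0))
        retained, tally = lnc.filter_cascade([rec])
        assert len(retained) == 0 and tally["orf_length"] == 1

    def test_default_design_retains_exactly_five(self):
        seqs, records, reads, labels = simulate_transcripts(seed=1)
        for r in records:
            r.distinct_smallrna = lnc.smallrna_hosting(r.sequence, reads)
        retained, tally = lnc.filter_cascade(records)
        assert len(retained) == 5
        assert {r.id for r in retained} == {t for t, lab in labels.items() if lab == "pass"}
        for r in records:
            if labels[r.id] != "pass":
                assert tally[labels[r.id]] >= 1

    def test_retained_set_is_order_independent(self):
        _, records, reads, _ = simulate_transcripts(seed=2)
        for r in records:
            r.distinct_smallrna = lnc.smallrna_hosting(r.sequence, reads)
        fwd, _ = lnc.filter_cascade(records)
        rev, _ = lnc.filter_cascade(records[::-1])
        assert {r.id for r in fwd} == {r.id for r in rev}


@pytest.fixture
def gene_ann():
    g = GeneModel(
        "pcg1",
        GenomicInterval("chr1", 10_000, 16_000, "+"),
        exons=(GenomicInterval("chr1", 10_000, 12_000, "+"),
               GenomicInterval("chr1", 14_000, 16_000, "+")),
    )
    return AnnotationSet(genes=[g])


class TestClassify:
    def test_intronic_same_strand(self, gene_ann):
        iv = GenomicInterval("chr1", 12_500, 13_000, "+")
        assert lnc.classify_lncrna(iv, gene_ann) == "intronic"

    def test_antisense_overlap(self, gene_ann):
        iv = GenomicInterval("chr1", 11_000, 11_500, "-")
        assert lnc.classify_lncrna(iv, gene_ann) == "antisense"

    def test_exonic_and_spanning(self, gene_ann):
        assert lnc.classify_lncrna(GenomicInterval("chr1", 10_100, 10_500, "+"), gene_ann) == "exonic"
        assert lnc.classify_lncrna(GenomicInterval("chr1", 11_500, 12_500, "+"), gene_ann) == "exon_intron"

    @pytest.mark.parametrize("start,expect", [
        (17_000, "intergenic_2kb"),    # 1 kb from gene end
        (21_000, "intergenic_10kb"),   # 5 kb away
        (40_000, "intergenic_far"),    # 24 kb away
    ])
    def test_intergenic_bins(self, gene_ann, start, expect):
        iv = GenomicInterval("chr1", start, start + 400, "+")
        assert lnc.classify_lncrna(iv, gene_ann) == expect


class TestEntropySpecificity:
    def test_uniform_is_zero(self):
        assert lnc.entropy_specificity(np.full(8, 3.0)) == pytest.approx(0.0)

    def test_one_hot_is_one(self):
        v = np.zeros(8)
        v[2] = 5.0
        assert lnc.entropy_specificity(v) == pytest.approx(1.0)

    def test_two_stage_hand_value(self):
        v = np.array([0.5, 0.5, 0, 0, 0, 0, 0, 0])
        assert lnc.entropy_specificity(v) == pytest.approx(1 - 1 / 3, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.random(8)
        assert lnc.entropy_specificity(v) == pytest.approx(lnc.entropy_specificity(17.3 * v))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lnc.entropy_specificity(np.zeros(8))


class TestBicor:
    def test_self_and_negated(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        assert lnc.bicor(x, x) == pytest.approx(1.0)
        assert lnc.bicor(x, -x) == pytest.approx(-1.0)

    def test_close_to_pearson_on_gaussian(self):
        rng = np.random.default_rng(1)
        n, rho = 1000, 0.7
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(lnc.bicor(x, y) - pearson) < 0.05

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert lnc.bicor(x, y) == pytest.approx(lnc.bicor(y, x))
        assert lnc.bicor(3 * x + 5, y) == pytest.approx(lnc.bicor(x, y), abs=1e-9)

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.warns(UserWarning, match="MAD"):
            r = lnc.bicor(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])


def _intergenic_setup(n_pairs, seed, target=0.95):
    """lncRNAs placed 1 kb downstream of their own gene, paired by expression."""
    genes = []
    lncs = []
    pairs = []
    for i in range(n_pairs):
        base = 20_000 * (i + 1)
        g = GeneModel(f"pcg{i}", GenomicInterval("chr1", base, base + 3000, "+"),
                      exons=(GenomicInterval("chr1", base, base + 3000, "+"),))
        genes.append(g)
        iv = GenomicInterval("chr1", base + 4000, base + 4500, "+")
        lncs.append((f"lnc{i}", iv))
        pairs.append((f"lnc{i}", f"pcg{i}", target))
    ids = [p[0] for p in pairs] + [p[1] for p in pairs]
    expr = simulate_expression(ids, pairs=pairs, seed=seed)
    ann = AnnotationSet(genes=genes)
    records = [
        lnc.TranscriptRecord(lid, "C" * 400, interval=iv, tpm=expr.loc[lid].to_numpy())
        for lid, iv in lncs
    ]
    gene_tpm = {g.id: expr.loc[g.id].to_numpy() for g in genes}
    return records, ann, gene_tpm


class TestPairCoexpression:
    def test_planted_pairs_retained(self):
        records, ann, gene_tpm = _intergenic_setup(6, seed=1)
        out = lnc.pair_coexpression(records, None, ann, gene_tpm)
        assert set(out["lncrna"]) == {r.id for r in records}
        assert (out["bicor"].abs() > 0.8).all()
        assert (out["class"] == "intergenic_2kb").all()

    def test_pair_distance_matches_interval_gap(self):
        records, ann, gene_tpm = _intergenic_setup(2, seed=2)
        out = lnc.pair_coexpression(records, None, ann, gene_tpm)
        assert (out["distance_bp"] == 1000).all()

    def test_independent_pairs_rarely_retained(self):
        """Unrelated profiles pass the |bicor| > 0.8 cutoff in < 5% of trials."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            x = np.log2(np.exp(rng.normal(1.5, 1.0, 8)) + 1)
            y = np.log2(np.exp(rng.normal(1.5, 1.0, 8)) + 1)
            hits += abs(lnc.bicor(x, y)) > 0.8
        assert hits < 5


class TestClusterModules:
    def test_two_planted_modules_recovered(self):
        rng = np.random.default_rng(4)
        t = np.arange(8, dtype=float)
        lat_a = np.sin(t)          # module A latent profile
        lat_b = np.cos(2 * t)      # module B latent profile
        lnc_tpm, gene_tpm, rows = {}, {}, []
        for i in range(3):
            for tag, lat in (("A", lat_a), ("B", lat_b)):
                prof = np.exp(2 + lat + rng.normal(0, 0.05, 8))
                lnc_tpm[f"l{tag}{i}"] = prof
                gene_tpm[f"g{tag}{i}"] = prof * np.exp(rng.normal(0, 0.05, 8))
                rows.append({"lncrna": f"l{tag}{i}", "gene": f"g{tag}{i}",
                             "class": "intergenic_2kb", "bicor": 0.95, "distance_bp": 100})
        import pandas as pd

        pairs = pd.DataFrame(rows)
        out = lnc.cluster_modules(pairs, lnc_tpm, gene_tpm)
        assert out["module"].nunique() == 2
        for tag in ("A", "B"):
            mods = out[out["lncrna"].str.startswith(f"l{tag}")]["module"]
            assert mods.nunique() == 1

    def test_single_pair_single_module(self):
        import pandas as pd

        pairs = pd.DataFrame([{"lncrna": "l", "gene": "g", "class": "intronic",
                               "bicor": 0.9, "distance_bp": 0}])
        out = lnc.cluster_modules(pairs, {"l": np.arange(8.0) + 1}, {"g": np.arange(8.0) + 2})
        assert out["module"].tolist() == [1]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        import pandas as pd

        lnc_tpm = {f"l{i}": np.exp(rng.normal(2, 1, 8)) for i in range(4)}
        gene_tpm = {f"g{i}": np.exp(rng.normal(2, 1, 8)) for i in range(4)}
        rows = [{"lncrna": f"l{i}", "gene": f"g{i}", "class": "intronic",
                 "bicor": 0.9, "distance_bp": 10} for i in range(4)]
        pairs = pd.DataFrame(rows)
        a = lnc.cluster_modules(pairs, lnc_tpm, gene_tpm)
        b = lnc.cluster_modules(pairs.iloc[::-1].reset_index(drop=True), lnc_tpm, gene_tpm)
        ma = dict(zip(a["lncrna"], a["module"]))
        mb = dict(zip(b["lncrna"], b["module"]))
        # same partition up to label names
        groups_a = {}
        for k, v in ma.items():
            groups_a.setdefault(v, set()).add(k)
        groups_b = {}
        for k, v in mb.items():
            groups_b.setdefault(v, set()).add(k)
        assert sorted(map(sorted, groups_a.values())) == sorted(map(sorted, groups_b.values()))
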