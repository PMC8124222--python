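import numpy as np
import pandas as pd
import pytest

from rrbsdmf.annotate import (
    GeneModel,
    annotate_fragments,
    classify_cgi_context,
    classify_gene_context,
    enrich_gene_set,
    genes_for_common_dmfs,
    overlap_features,
    promoter_interval,
    read_bed_intervals,
    read_gene_models,
    read_gmt,
)
from rrbsdmf.digest import GenomeFragment

from oracles import hypergeom_tail_enumeration


def bed(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


class TestPromoterInterval:
    def test_plus_strand_window(self):
        gene = GeneModel("G", "c", 5000, 9000, "+", ((5000, 9000),))
        assert promoter_interval(gene) == (3000, 6000)

    def test_minus_strand_mirrored_window(self):
        gene = GeneModel("G", "c", 1000, 5001, "-", ((1000, 5001),))
        assert gene.tss == 5000
        assert promoter_interval(gene) == (4001, 7001)

    def test_clipping_at_origin_and_contig_end(self):
        gene = GeneModel("G", "c", 500, 3000, "+", ((500, 3000),))
        assert promoter_interval(gene) == (0, 1500)
        minus = GeneModel("G", "c", 4000, 5901, "-", ((4000, 5901),))  # TSS 5900
        assert promoter_interval(minus, contig_length=6000) == (4901, 6000)


def two_exon_gene(name="G", contig="c", start=10_000, end=16_000, strand="+"):
    # exon1 [10000,11000), intron [11000,14000), exon2 [14000,16000)
    return GeneModel(name, contig, start, end, strand, ((start, start + 1000), (start + 4000, end)))


class TestGeneContext:
    def test_promoter_beats_exon(self):
        gene = two_exon_gene()
        frag = GenomeFragment("c", 10_100, 10_200)  # inside exon 1 and promoter window
        assert classify_gene_context(frag, [gene]) == ("promoter", "G")

    def test_junction_beats_exon_and_intron(self):
        gene = two_exon_gene()
        frag = GenomeFragment("c", 13_950, 14_050)  # spans intron/exon2 boundary
        assert classify_gene_context(frag, [gene]) == ("junction", "G")

    def test_exon_and_intron_contexts(self):
        gene = two_exon_gene()
        assert classify_gene_context(GenomeFragment("c", 14_500, 14_600), [gene]) == ("exon", "G")
        assert classify_gene_context(GenomeFragment("c", 12_000, 12_100), [gene]) == ("intron", "G")

    def test_intergenic_far_from_any_gene(self):
        gene = two_exon_gene()
        frag = GenomeFragment("c", 50_000, 50_100)
        assert classify_gene_context(frag, [gene]) == ("intergenic", None)

    def test_tie_breaks_by_tss_distance_then_name(self):
        near = GeneModel("ZZZ", "c", 10_000, 13_000, "+", ((10_000, 13_000),))
        # minus-strand gene, TSS 8000, promoter [7001, 10001): also covers frag
        far = GeneModel("AAA", "c", 5_000, 8_001, "-", ((5_000, 8_001),))
        frag = GenomeFragment("c", 9_500, 9_600)  # in both promoters; ZZZ's TSS closer
        assert classify_gene_context(frag, [near, far]) == ("promoter", "ZZZ")
        twin = GeneModel("AAA", "c", 10_000, 13_000, "+", ((10_000, 13_000),))
        assert classify_gene_context(frag, [near, twin]) == ("promoter", "AAA")

    def test_partition_sums_to_one(self, standard_artifacts):
        genes = [
            GeneModel(r.gene_name, r.contig, r.start, r.end, r.strand, tuple(r.exons))
            for r in standard_artifacts.genes.itertuples(index=False)
        ]
        annotations = annotate_fragments(
            standard_artifacts.fragments, genes, standard_artifacts.islands
        )
        gene_props = annotations["gene_context"].value_counts(normalize=True)
        cgi_props = annotations["cgi_context"].value_counts(normalize=True)
        assert gene_props.sum() == pytest.approx(1.0)
        assert cgi_props.sum() == pytest.approx(1.0)
        assert len(annotations) == len(standard_artifacts.fragments)


class TestCgiContext:
    islands = bed([("c", 10_000, 11_000)])

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (10_500, 10_600, "core"),
            (11_500, 11_600, "shore"),
            (13_500, 13_600, "shelf"),
            (20_000, 20_100, "open_sea"),
            (9_990, 10_010, "core"),       # 1 bp overlap counts
            (12_990, 13_010, "shore"),     # touches the 2 kb flank boundary
            (14_990, 15_010, "shelf"),     # touches the 4 kb flank boundary
        ],
    )
    def test_contexts(self, start, end, expected):
        frag = GenomeFragment("c", start, end)
        assert classify_cgi_context(frag, self.islands) == expected

    def test_other_contig_is_open_sea(self):
        frag = GenomeFragment("other", 10_500, 10_600)
        assert classify_cgi_context(frag, self.islands) == "open_sea"


class TestOverlapFeatures:
    frags = [GenomeFragment("c", 0, 10), GenomeFragment("c", 20, 30)]

    def test_identical_features_fraction_one(self):
        _, frac = overlap_features(self.frags, bed([("c", 0, 10), ("c", 20, 30)]))
        assert frac == 1.0

    def test_disjoint_features_fraction_zero(self):
        _, frac = overlap_features(self.frags, bed([("c", 100, 200)]))
        assert frac == 0.0

    def test_partial_overlap(self):
        flags, frac = overlap_features(self.frags, bed([("c", 5, 6)]))
        assert frac == 0.5 and list(flags) == [True, False]


class TestGenesForCommonDmfs:
    annotations = pd.DataFrame(
        {
            "fragment_id": ["f1", "f2", "f3", "f4"],
            "gene_context": ["promoter", "promoter", "intron", "intergenic"],
            "gene": ["A", "A", "A", None],
            "cgi_context": ["core"] * 4,
        }
    )

    def test_promoter_set_deduplicated(self):
        common = pd.DataFrame({"fragment_id": ["f1", "f2"]})
        sets = genes_for_common_dmfs(common, self.annotations)
        assert sets["promoter"] == {"A"} and sets["body"] == set()

    def test_both_context_gene(self):
        common = pd.DataFrame({"fragment_id": ["f1", "f3"]})
        sets = genes_for_common_dmfs(common, self.annotations)
        assert sets == {"promoter": {"A"}, "body": {"A"}, "both": {"A"}}

    def test_empty(self):
        sets = genes_for_common_dmfs(pd.DataFrame({"fragment_id": []}), self.annotations)
        assert sets == {"promoter": set(), "body": set(), "both": set()}


class TestEnrichment:
    def test_query_equals_background_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        out = enrich_gene_set(genes, genes, {"S": set(genes)})
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_single_extreme_term(self):
        background = [f"g{i}" for i in range(50)]
        target = set(background[:5])
        out = enrich_gene_set(background[:5], background, {"S": target})
        from math import comb

        assert out.iloc[0]["p_value"] == pytest.approx(1 / comb(50, 5), rel=1e-10)

    def test_zero_overlap_gives_p_one(self):
        background = [f"g{i}" for i in range(20)]
        out = enrich_gene_set(background[:3], background, {"S": set(background[10:])})
        assert out.iloc[0]["p_value"] == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        background = [f"g{i}" for i in range(60)]
        query = list(rng.choice(background, 12, replace=False))
        library = {
            f"S{j}": set(rng.choice(background, int(rng.integers(5, 25)), replace=False))
            for j in range(8)
        }
        out = enrich_gene_set(query, background, library).set_index("set")
        for name, genes in library.items():
            k = len(genes & set(query))
            expected = hypergeom_tail_enumeration(60, len(genes), 12, k)
            assert out.loc[name, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        background = [f"g{i}" for i in range(100)]
        query = list(rng.choice(background, 20, replace=False))
        library = {
            f"S{j}": set(rng.choice(background, 30, replace=False)) for j in range(10)
        }
        out = enrich_gene_set(query, background, library)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()
        assert out["p_adjusted"].is_monotonic_increasing

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_gene_set(["x"], ["a", "b"], {})
        with pytest.raises(ValueError):
            enrich_gene_set([], [], {})


def test_gtf_roundtrip_and_gmt(tmp_path, standard_artifacts):
    from rrbsdmf.simulate import write_gtf

    gtf = tmp_path / "genes.gtf"
    write_gtf(standard_artifacts.genes, gtf)
    genes = read_gene_models(gtf)
    assert len(genes) == len(standard_artifacts.genes)
    by_name = {g.name: g for g in genes}
    for row in standard_artifacts.genes.itertuples(index=False):
        g = by_name[row.gene_name]
        assert (g.start, g.end, g.strand) == (row.start, row.end, row.strand)
        assert g.exons == tuple(row.exons)

    gmt = tmp_path / "sets.gmt"
    gmt.write_text("S1\tdesc\tA\tB\nS2\tdesc\tC\n")
    assert read_gmt(gmt) == {"S1": {"A", "B"}, "S2": {"C"}}

    bed_path = tmp_path / "x.bed"
    bed_path.write_text("c\t10\t20\nc\t1\t5\n")
    frame = read_bed_intervals(bed_path)
    assert frame["start"].tolist() == [1, 10]  # sorted internally
    bad = tmp_path / "bad.bed"
    bad.write_text("c\t10\t20\nc\toops\t5\n")
    with pytest.raises(ValueError, match="bad.bed:2"):
        read_bed_intervals(bad)
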