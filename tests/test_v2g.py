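"""Chromatin variant-to-gene mapping: promoter windows and anchor logic."""

import pytest

from gwas2gene import map_candidates_to_genes, promoter_interval
from gwas2gene.intervals import GenomicInterval
from gwas2gene.model import InteractionPair

from conftest import make_gene, make_variant


class TestPromoterInterval:
    def test_plus_strand_window(self):
        g = make_gene("g", "chr1", 9_000, 20_000, "+", tss=10_001)
        assert promoter_interval(g, 2_000, 500) == GenomicInterval("chr1", 8_000, 10_500)

    def test_minus_strand_window(self):
        g = make_gene("g", "chr1", 2_000, 12_001, "-", tss=10_001)
        assert promoter_interval(g, 2_000, 500) == GenomicInterval("chr1", 9_501, 12_001)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_minimal_window_contains_tss_base(self, strand):
        g = make_gene("g", "chr1", 9_000, 20_000, strand, tss=10_001)
        win = promoter_interval(g, 1, 1)
        assert win.width == 2
        assert win.contains_base("chr1", 10_000)  # 0-based TSS

    def test_clipped_at_zero(self):
        g = make_gene("g", "chr1", 0, 5_000, "+", tss=100)
        assert promoter_interval(g, 2_000, 500).start == 0

    def test_empty_window_rejected(self):
        g = make_gene("g", "chr1", 0, 5_000, "+", tss=100)
        with pytest.raises(ValueError):
            promoter_interval(g, 0, 0)


@pytest.fixture()
def scene():
    """One candidate at 1-based 150, one gene whose promoter sits in [40k, 42.5k)."""
    gene = make_gene("geneX", "chr1", 41_999, 60_000, "+", tss=42_000)
    candidates = {"v": make_variant("v", "chr1", 150)}
    return candidates, [gene]


def pair(a, b, tissue="T1"):
    return InteractionPair(tissue, GenomicInterval(*a), GenomicInterval(*b))


class TestMapping:
    def test_variant_in_anchor_promoter_in_partner(self, scene):
        candidates, genes = scene
        links = map_candidates_to_genes(
            candidates, [pair(("chr1", 100, 200), ("chr1", 40_000, 45_000))], genes
        )
        assert [(l.variant_id, l.gene_id, l.tissue_id) for l in links] == [("v", "geneX", "T1")]

    def test_anchor_symmetry(self, scene):
        candidates, genes = scene
        fwd = [pair(("chr1", 100, 200), ("chr1", 40_000, 45_000))]
        rev = [pair(("chr1", 40_000, 45_000), ("chr1", 100, 200))]
        as_links = lambda ls: {(l.variant_id, l.gene_id, l.tissue_id) for l in ls}
        assert as_links(map_candidates_to_genes(candidates, fwd, genes)) == as_links(
            map_candidates_to_genes(candidates, rev, genes)
        )

    def test_same_anchor_cooccurrence_is_not_a_link(self):
        # variant and promoter inside anchor A; partner anchor overlaps neither
        gene = make_gene("geneX", "chr1", 1_999, 9_000, "+", tss=2_000)
        candidates = {"v": make_variant("v", "chr1", 150)}
        links = map_candidates_to_genes(
            candidates, [pair(("chr1", 0, 5_000), ("chr1", 100_000, 105_000))], [gene]
        )
        assert links == []

    def test_trans_pairs_excluded_by_default(self, scene):
        candidates, genes = scene
        trans = [pair(("chr1", 100, 200), ("chr1", 40_000, 45_000), "T1"),
                 pair(("chr2", 100, 200), ("chr1", 40_000, 45_000), "T1")]
        assert len(map_candidates_to_genes(candidates, trans, genes)) == 1

    def test_trans_inclusion_switch(self):
        gene = make_gene("geneX", "chr2", 41_999, 60_000, "+", tss=42_000)
        candidates = {"v": make_variant("v", "chr1", 150)}
        pairs = [pair(("chr1", 100, 200), ("chr2", 40_000, 45_000))]
        assert map_candidates_to_genes(candidates, pairs, [gene]) == []
        links = map_candidates_to_genes(candidates, pairs, [gene], include_trans=True)
        assert len(links) == 1

    def test_min_score_filter(self, scene):
        candidates, genes = scene
        p = pair(("chr1", 100, 200), ("chr1", 40_000, 45_000))
        p.score = 2.0
        assert map_candidates_to_genes(candidates, [p], genes, min_score=5.0) == []
        assert len(map_candidates_to_genes(candidates, [p], genes, min_score=1.0)) == 1

    def test_duplicate_pairs_deduplicate_links(self, scene):
        candidates, genes = scene
        p = pair(("chr1", 100, 200), ("chr1", 40_000, 45_000))
        links = map_candidates_to_genes(candidates, [p, p], genes)
        assert len(links) == 1 and links[0].interaction_index == 0

    def test_variant_base_boundary_in_anchor(self, scene):
        candidates = {"edge": make_variant("edge", "chr1", 200)}
        _, genes = scene
        inside = map_candidates_to_genes(
            candidates, [pair(("chr1", 100, 200), ("chr1", 40_000, 45_000))], genes
        )
        assert len(inside) == 1  # base [199, 200) is the last base of the anchor
        candidates = {"out": make_variant("out", "chr1", 201)}
        outside = map_candidates_to_genes(
            candidates, [pair(("chr1", 100, 200), ("chr1", 40_000, 45_000))], genes
        )
        assert outside == []

    def test_enlarging_promoter_window_never_removes_links(self, bundle):
        _, truth, data = bundle
        small = map_candidates_to_genes(
            data["index"],
            [p for ps in data["interactions"].values() for p in ps],
            data["genes"], up_bp=2_000, down_bp=500,
        )
        big = map_candidates_to_genes(
            data["index"],
            [p for ps in data["interactions"].values() for p in ps],
            data["genes"], up_bp=10_000, down_bp=5_000,
        )
        key = lambda ls: {(l.variant_id, l.gene_id, l.tissue_id) for l in ls}
        assert key(small) <= key(big)

    def test_planted_links_recovered_exactly(self, bundle):
        _, truth, data = bundle
        links = map_candidates_to_genes(
            data["index"],
            [p for ps in data["interactions"].values() for p in ps],
            data["genes"],
        )
        recovered = {(l.variant_id, l.gene_id, l.tissue_id) for l in links}
        assert recovered == set(truth.planted_interaction_links)
        # distinct-gene count equals the union of gene ids over links
        assert len({l.gene_id for l in links}) == len({g for _, g, _ in recovered})
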