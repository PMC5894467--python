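"""eQTL joining, evidence tiers, druggability and the run summary."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwas2gene import (
    DrugGeneRecord,
    DruggabilityRecord,
    EqtlRecord,
    GeneEvidence,
    Locus,
    V2GLink,
    annotate_druggability,
    classify_gene_position,
    eqtl_gene_links,
    integrate_evidence,
    summarize_counts,
)
from gwas2gene.intervals import GenomicInterval

from conftest import make_gene, make_variant


CANDIDATES = {"rs1": make_variant("rs1", "chr1", 100)}


class TestEqtlLinks:
    def test_significant_candidate_record_links(self):
        eqtls = [EqtlRecord("rs1", "geneA", "artery", 0.3, qvalue=0.01)]
        assert eqtl_gene_links(CANDIDATES, eqtls, q_max=0.05) == {("rs1", "geneA", "artery")}

    def test_boundary_q_is_inclusive(self):
        eqtls = [EqtlRecord("rs1", "geneA", "artery", 0.3, qvalue=0.05)]
        assert len(eqtl_gene_links(CANDIDATES, eqtls, q_max=0.05)) == 1

    def test_non_candidate_variant_never_links(self):
        eqtls = [EqtlRecord("rs99", "geneA", "artery", 0.3, qvalue=0.001)]
        assert eqtl_gene_links(CANDIDATES, eqtls) == set()

    def test_significance_flag_governs_without_qvalue(self):
        eqtls = [
            EqtlRecord("rs1", "geneA", "artery", 0.3, significant=True),
            EqtlRecord("rs1", "geneB", "artery", 0.3, significant=False),
        ]
        assert eqtl_gene_links(CANDIDATES, eqtls) == {("rs1", "geneA", "artery")}

    def test_tissue_whitelist_restricts(self):
        eqtls = [
            EqtlRecord("rs1", "geneA", "artery", 0.3, qvalue=0.01),
            EqtlRecord("rs1", "geneB", "spleen", 0.3, qvalue=0.01),
        ]
        links = eqtl_gene_links(CANDIDATES, eqtls, tissues=["artery", "kidney"])
        assert links == {("rs1", "geneA", "artery")}

    def test_bad_q_max_rejected(self):
        with pytest.raises(ValueError):
            eqtl_gene_links(CANDIDATES, [], q_max=0.0)


class TestIntegrate:
    def test_three_way_tier_assignment(self):
        hic = [V2GLink("rs1", "geneA", "T1"), V2GLink("rs1", "geneB", "T2")]
        eqtl = {("rs1", "geneA", "artery"), ("rs2", "geneC", "artery")}
        evidence, counts = integrate_evidence(hic, eqtl)
        tiers = {e.gene_id: e.tier for e in evidence}
        assert tiers == {"geneA": "BOTH", "geneB": "HIC_ONLY", "geneC": "EQTL_ONLY"}
        assert (counts.n_hic, counts.n_confirmed, counts.n_added, counts.n_total) == (2, 1, 1, 3)

    def test_empty_eqtl_set_degenerates(self):
        hic = [V2GLink("rs1", "geneA", "T1")]
        _, counts = integrate_evidence(hic, set())
        assert (counts.n_confirmed, counts.n_added, counts.n_total) == (0, 0, counts.n_hic)

    def test_order_invariance(self):
        hic = [V2GLink("rs1", "geneA", "T1"), V2GLink("rs2", "geneB", "T2"),
               V2GLink("rs3", "geneA", "T3")]
        eqtl = [("rs1", "geneA", "a"), ("rs9", "geneD", "b")]
        ev1, c1 = integrate_evidence(hic, eqtl)
        shuffled = hic[::-1]
        random.Random(0).shuffle(eqtl)
        ev2, c2 = integrate_evidence(shuffled, eqtl)
        assert ev1 == ev2 and c1 == c2

    def test_reintegration_with_no_new_links_is_a_noop(self):
        hic = [V2GLink("rs1", "geneA", "T1")]
        eqtl = {("rs1", "geneA", "artery")}
        ev1, c1 = integrate_evidence(hic, eqtl)
        ev2, c2 = integrate_evidence(hic, eqtl | set())
        assert ev1 == ev2 and c1 == c2

    @given(
        hic=st.sets(st.tuples(st.sampled_from("vwxyz"), st.sampled_from("ABCDEFG"),
                              st.sampled_from("pq")), max_size=20),
        eqtl=st.sets(st.tuples(st.sampled_from("vwxyz"), st.sampled_from("ABCDEFG"),
                               st.sampled_from("pq")), max_size=20),
    )
    @settings(max_examples=80, derandomize=True)
    def test_tier_conservation_on_every_input(self, hic, eqtl):
        links = [V2GLink(v, g, t) for v, g, t in hic]
        _, counts = integrate_evidence(links, eqtl)
        assert counts.n_total == counts.n_hic + counts.n_added
        assert counts.n_confirmed <= counts.n_hic


def _evidence(gene_ids):
    evs = [GeneEvidence(g, interaction_tissues={"T1"}) for g in gene_ids]
    for e in evs:
        e.assign_tier()
    return evs


class TestDruggability:
    def test_tier_intersection_count(self):
        evs = _evidence(["g1", "g2", "g3", "g4", "g5"])
        table = [DruggabilityRecord("g2", "TIER1"), DruggabilityRecord("g4", "TIER3"),
                 DruggabilityRecord("g9", "TIER1")]
        annotate_druggability(evs, table)
        assert sum(e.druggability.tier != "NONE" for e in evs) == 2

    def test_atc_prefix_sets_antihypertensive_flag(self):
        evs = _evidence(["geneX", "geneY"])
        drugs = [DrugGeneRecord("geneX", "irbesartan", "C09CA04"),
                 DrugGeneRecord("geneY", "metformin", "A10BA02")]
        annotate_druggability(evs, [DruggabilityRecord("geneX", "TIER1")], drugs)
        flags = {e.gene_id: e.antihypertensive for e in evs}
        assert flags == {"geneX": True, "geneY": False}

    def test_empty_druggable_table_means_all_none(self):
        evs = _evidence(["g1", "g2"])
        annotate_druggability(evs, [])
        assert all(e.druggability.tier == "NONE" for e in evs)


class TestGenePosition:
    @pytest.mark.parametrize(
        "region,expected",
        [((8_999, 20_000), True), ((9_000, 20_000), False)],
    )
    def test_half_open_overlap_with_locus_region(self, region, expected):
        gene = make_gene("g1", "chr1", 5_000, 9_000)
        locus = Locus("rs1", GenomicInterval("chr1", *region), frozenset({"rs1"}))
        evs = _evidence(["g1"])
        classify_gene_position(evs, [locus], [gene])
        assert evs[0].inside_locus is expected

    def test_position_partition_and_unknowns(self):
        genes = [make_gene("g1", "chr1", 5_000, 9_000), make_gene("g2", "chr1", 50_000, 60_000)]
        locus = Locus("rs1", GenomicInterval("chr1", 8_000, 20_000), frozenset({"rs1"}))
        evs = _evidence(["g1", "g2", "g3"])  # g3 has no gene model
        classify_gene_position(evs, [locus], genes)
        summary = summarize_counts(evs)
        assert summary.n_inside_loci == 1
        assert summary.n_outside_loci == 1
        assert summary.n_unknown_position == 1
        assert summary.n_inside_loci + summary.n_outside_loci + summary.n_unknown_position \
            == summary.n_total


class TestSummary:
    def test_empty_evidence_all_zero(self):
        s = summarize_counts([])
        assert all(v == 0 for v in s.as_dict().values())

    def test_summary_is_pure_recomputation(self, bundle):
        _, truth, data = bundle
        from gwas2gene import run_bundle

        result = run_bundle(bundle[0])
        again = summarize_counts(result.evidence, result.tier_counts,
                                 n_candidates=len(result.candidates))
        assert again == result.summary
        assert result.summary.n_antihypertensive <= result.summary.n_total
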