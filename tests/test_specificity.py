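"""Tissue-specificity enrichment: hit counting, shift null, ranking."""

import numpy as np
import pytest

from gwas2gene import (
    Locus,
    PeakTrack,
    count_loci_hit,
    permutation_null,
    rank_tissues,
)
from gwas2gene.intervals import GenomicInterval

from conftest import make_variant


def make_track(tissue, triples):
    return PeakTrack(tissue, "H3K4me3", [(GenomicInterval(*t), None) for t in triples])


def make_locus(lead_id, candidate_ids, chrom, lo, hi):
    return Locus(lead_id, GenomicInterval(chrom, lo, hi), frozenset(candidate_ids))


@pytest.fixture()
def one_locus():
    variants = {
        "rs1": make_variant("rs1", "chr1", 150),
        "rs2": make_variant("rs2", "chr1", 151),
    }
    locus = make_locus("rs1", {"rs1", "rs2"}, "chr1", 100, 200)
    return [locus], variants


def exact_shift_hit_rate(positions, peaks, shift_bp):
    """Independent oracle: enumerate every integer offset in [-s, s].

    Applies the same reflection-at-1 rule and checks base membership by a
    direct scan over raw (start, end) peak tuples.
    """
    n_hit = 0
    offsets = range(-shift_bp, shift_bp + 1)
    for d in offsets:
        shifted = [2 - (p + d) if p + d < 1 else p + d for p in positions]
        if any(s <= p - 1 < e for p in shifted for s, e in peaks):
            n_hit += 1
    return n_hit / len(offsets)


class TestCountLociHit:
    def test_locus_contributes_at_most_one(self, one_locus):
        loci, variants = one_locus
        assert count_loci_hit(loci, variants, make_track("T", [("chr1", 100, 200)])) == 1

    def test_half_open_boundary_of_peak(self):
        variants = {"a": make_variant("a", "chr1", 200), "b": make_variant("b", "chr1", 201)}
        track = make_track("T", [("chr1", 100, 200)])
        hit = [make_locus("a", {"a"}, "chr1", 150, 250)]
        miss = [make_locus("b", {"b"}, "chr1", 150, 250)]
        # 1-based 200 occupies [199, 200) -> inside; 201 -> [200, 201) -> outside
        assert count_loci_hit(hit, variants, track) == 1
        assert count_loci_hit(miss, variants, track) == 0

    def test_empty_track_counts_zero(self, one_locus):
        loci, variants = one_locus
        assert count_loci_hit(loci, variants, make_track("T", [])) == 0

    def test_unresolvable_candidate_is_named(self, one_locus):
        loci, variants = one_locus
        bad = [make_locus("rs1", {"rs1", "ghost"}, "chr1", 100, 200)]
        with pytest.raises(KeyError, match="ghost"):
            count_loci_hit(bad, variants, make_track("T", []))


class TestPermutationNull:
    def test_saturating_track_pins_null_at_n_loci(self, one_locus):
        loci, variants = one_locus
        track = make_track("T", [("chr1", 0, 10_000_000)])
        null = permutation_null(loci, variants, track, B=50, shift_bp=1_000, seed=3)
        assert (null == len(loci)).all()

    def test_empty_track_gives_all_zero(self, one_locus):
        loci, variants = one_locus
        null = permutation_null(loci, variants, make_track("T", []), B=50,
                                shift_bp=1_000, seed=3)
        assert (null == 0).all()

    def test_same_seed_reproduces_null_vector(self, one_locus):
        loci, variants = one_locus
        track = make_track("T", [("chr1", 120, 180)])
        a = permutation_null(loci, variants, track, B=200, shift_bp=500, seed=11)
        b = permutation_null(loci, variants, track, B=200, shift_bp=500, seed=11)
        assert (a == b).all()

    def test_parameter_validation(self, one_locus):
        loci, variants = one_locus
        track = make_track("T", [])
        with pytest.raises(ValueError):
            permutation_null(loci, variants, track, B=0)
        with pytest.raises(ValueError):
            permutation_null(loci, variants, track, shift_bp=0)

    def test_mean_matches_exhaustive_enumeration(self):
        # single locus, two candidates 7 bp apart, one 20 bp peak, shift 50
        positions = [500, 507]
        peaks = [(520, 540)]
        variants = {f"v{p}": make_variant(f"v{p}", "chr1", p) for p in positions}
        loci = [make_locus("v500", set(variants), "chr1", 400, 600)]
        track = make_track("T", [("chr1", s, e) for s, e in peaks])
        exact = exact_shift_hit_rate(positions, peaks, 50)
        B = 4_000
        null = permutation_null(loci, variants, track, B=B, shift_bp=50, seed=5)
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(null.mean() - exact) <= 3 * se

    def test_reflection_at_origin_matches_enumeration(self):
        # candidate close to position 1: shifts below 1 reflect (pos -> 2 - pos)
        positions = [30]
        peaks = [(0, 15)]
        variants = {"v": make_variant("v", "chr1", 30)}
        loci = [make_locus("v", {"v"}, "chr1", 0, 60)]
        track = make_track("T", [("chr1", 0, 15)])
        exact = exact_shift_hit_rate(positions, peaks, 50)
        B = 4_000
        null = permutation_null(loci, variants, track, B=B, shift_bp=50, seed=6)
        se = np.sqrt(exact * (1 - exact) / B) + 1e-12
        assert abs(null.mean() - exact) <= 3 * se + 1e-9


class TestRankTissues:
    def test_identical_tracks_tie_broken_by_tissue_id(self, one_locus):
        loci, variants = one_locus
        tracks = [make_track(t, [("chr1", 120, 180)]) for t in ("T2", "T1")]
        ranked = rank_tissues(loci, variants, tracks, B=99, shift_bp=500, seed=2)
        assert [r.tissue_id for r in ranked] == ["T1", "T2"]
        assert ranked[0].p_emp == ranked[1].p_emp
        assert [r.rank for r in ranked] == [1, 2]

    def test_extreme_observation_hits_the_p_floor(self):
        # peak exactly on the candidate but nowhere else in the shift range
        variants = {"v": make_variant("v", "chr1", 1_000_000)}
        loci = [make_locus("v", {"v"}, "chr1", 999_000, 1_001_000)]
        track = make_track("T", [("chr1", 999_999, 1_000_000)])
        B = 199
        ranked = rank_tissues(loci, variants, [track], B=B, shift_bp=400_000, seed=4)
        assert ranked[0].p_emp == pytest.approx(1 / (B + 1))

    def test_saturating_track_gives_fold_one_p_one(self, one_locus):
        loci, variants = one_locus
        track = make_track("T", [("chr1", 0, 10_000_000)])
        ranked = rank_tissues(loci, variants, [track], B=99, shift_bp=1_000, seed=1)
        assert ranked[0].fold == pytest.approx(1.0)
        assert ranked[0].p_emp == pytest.approx(1.0)

    def test_p_never_zero_and_bh_monotone(self, bundle):
        _, truth, data = bundle
        tracks = list(data["tracks"].values())
        ranked = rank_tissues(data["loci"], data["index"], tracks, B=99,
                              shift_bp=200_000, seed=9)
        assert all(r.p_emp >= 1 / 100 for r in ranked)
        qs = [r.q_bh for r in sorted(ranked, key=lambda r: r.p_emp)]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert sorted(r.rank for r in ranked) == list(range(1, len(ranked) + 1))

    def test_input_order_does_not_matter(self, one_locus):
        loci, variants = one_locus
        tracks = [make_track("T1", [("chr1", 120, 180)]), make_track("T2", [])]
        a = rank_tissues(loci, variants, tracks, B=99, shift_bp=500, seed=2)
        b = rank_tissues(loci, variants, tracks[::-1], B=99, shift_bp=500, seed=2)
        assert [(r.tissue_id, r.p_emp) for r in a] == [(r.tissue_id, r.p_emp) for r in b]

    def test_planted_enrichment_ranks_first(self, bundle):
        _, truth, data = bundle
        tracks = list(data["tracks"].values())
        ranked = rank_tissues(data["loci"], data["index"], tracks, B=199,
                              shift_bp=500_000, seed=13)
        top = {r.tissue_id for r in ranked[: len(truth.enriched_tissues)]}
        assert top == set(truth.enriched_tissues)
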