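"""Rank tissues by enrichment of candidate SNPs in their peak tracks.

The statistic is the number of loci with at least one candidate inside a
peak; its null comes from shifting each locus's candidates by a uniform
random offset (spacing preserved) and recounting, B times.
"""

from gwas2gene import rank_tissues, simulate_bundle

_, truth, data = simulate_bundle(seed=1)

ranked = rank_tissues(
    data["loci"], data["index"], list(data["tracks"].values()),
    B=999, shift_bp=500_000, seed=1,
)
print(f"{'tissue':8} {'hits':>4} {'null':>6} {'fold':>6} {'p':>7} {'q':>7} rank")
for r in ranked:
    print(f"{r.tissue_id:8} {r.observed_hits:4d} {r.null_mean:6.2f} "
          f"{r.fold:6.2f} {r.p_emp:7.4f} {r.q_bh:7.4f} {r.rank:4d}")
print(f"\nplanted enrichment was in: {sorted(truth.enriched_tissues)}")
# The planted tissues should head the table with p at the 1/(B+1) floor;
# the others hit peaks only at the background rate.
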