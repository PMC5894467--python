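"""Generate a synthetic input bundle and inspect its ground truth.

The bundle is a directory of plain-text files — lead-SNP and LD-proxy
tables, gene models, per-tissue H3K4me3 peak tracks (BED), chromatin
interaction pairs (BEDPE), eQTL records, CADD scores and druggability
tables — plus a truth.json recording exactly what was planted.
"""

from gwas2gene import SimParams, simulate_bundle

manifest, truth, data = simulate_bundle(SimParams(), seed=1, outdir="scratch/demo_bundle")

print(f"wrote {len(manifest)} files to scratch/demo_bundle/")
print(f"candidate SNPs planted: {len(truth.candidate_ids)}")
print(f"tissues with planted enrichment: {truth.enriched_tissues}")
print(f"planted interaction links: {len(truth.planted_interaction_links)}")
print("expected end-of-pipeline counts:", truth.expected_counts)
# The expected counts are what a perfect analysis of these files must
# report; the other examples recompute them from the files alone.
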