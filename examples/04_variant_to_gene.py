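"""Map candidate SNPs to genes through chromatin-interaction anchors.

A link (variant, gene, tissue) requires an interaction pair with the
variant's base in one anchor and the gene's promoter window (strand-aware,
2 kb up / 0.5 kb down of the TSS by default) overlapping the other.
"""

from gwas2gene import map_candidates_to_genes, simulate_bundle

_, truth, data = simulate_bundle(seed=1)
pairs = [p for ps in data["interactions"].values() for p in ps]

links = map_candidates_to_genes(data["index"], pairs, data["genes"])

print(f"{len(pairs)} interaction pairs -> {len(links)} links, "
      f"{len({l.gene_id for l in links})} distinct genes")
for l in links[:5]:
    print(f"  {l.variant_id} -> {l.gene_id} in {l.tissue_id}")
recovered = {(l.variant_id, l.gene_id, l.tissue_id) for l in links}
print("recovered exactly the planted links:",
      recovered == set(truth.planted_interaction_links))
# With zero background interactions the mapping is exact: every planted
# link is found and nothing else.
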