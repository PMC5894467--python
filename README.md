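# gwas2gene

Integrative interpretation of blood-pressure GWAS loci. Genome-wide
association studies have reported on the order of 900 index variants for
systolic/diastolic blood pressure, pulse pressure and hypertension, yet
~90% of them are intronic or intergenic: the association tags a regulatory
region, not a gene. `gwas2gene` implements the standard regulome-based
route from such loci to candidate drug targets:

1. **Candidate expansion** — each lead SNP becomes a locus with a
   candidate set, from an LD-proxy table (r² ≥ 0.8 by default) or a
   ±50 kb window fallback.
2. **Functional annotation** — exonic/intronic/intergenic classification
   against gene models, plus the CADD PHRED > 12.37 deleteriousness filter.
3. **Cell-type specificity** — per-tissue enrichment of candidates in peak
   tracks (H3K4me3, DHS, ...). The statistic is the number of loci with
   ≥ 1 candidate in a peak; the null shifts each locus's candidates by a
   uniform random offset in ±500 kb (spacing preserved), B = 1000 times:
   p = (1 + #{null ≥ obs}) / (B + 1), Benjamini–Hochberg across tissues.
4. **Variant-to-gene mapping** — a candidate links to a gene when a
   chromatin-interaction pair (Hi-C/BEDPE) holds the SNP in one anchor and
   the gene's strand-aware promoter window (2 kb up / 0.5 kb down of the
   TSS) in the other.
5. **eQTL integration** — significant candidate eQTLs (q ≤ 0.05) confirm
   interaction-mapped genes ("BOTH") or add eQTL-only genes; always
   n_total = n_hic + n_added.
6. **Druggability report** — druggable-genome tiers, drug–gene
   interactions with antihypertensive ATC prefixes (C02/C03/C07/C08/C09),
   and inside/outside-locus classification of every mapped gene.

A synthetic-data generator (`simulate_bundle`) produces a complete,
self-consistent plain-text input bundle with a machine-readable ground
truth, so every stage is testable without downloading Roadmap/GTEx/Hi-C
resources. Real supplementary tables in the documented TSV/BED/BEDPE
schemas drop into the same pipeline.

## Worked example

```python
from gwas2gene import run_bundle, simulate_bundle

simulate_bundle(seed=1, outdir="demo_bundle")   # writes 25 text files
result = run_bundle("demo_bundle")
print(result.summary)
```

prints (seed 1):

```
candidate SNPs:                106
Hi-C mapped genes:             30
  confirmed by eQTL:           9
eQTL-only (added) genes:       10
total mapped genes:            40
druggable:                     12
antihypertensive-interacting:  2
outside associated loci:       38
```

106 candidate SNPs (40 leads plus their r² ≥ 0.8 proxies) map to 30 genes
through interaction anchors; eQTL evidence confirms 9 of them and adds 10
more, for 40 genes in total, of which 12 are in the druggable genome, 2
interact with an antihypertensive-class drug, and 38 lie physically
outside the associated loci — the signature of long-range regulation.
Because this bundle is noise-free, these numbers equal the generator's
planted truth exactly. The `examples/` scripts walk each stage
individually (tissue ranking, mapping, annotation) with commentary.

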