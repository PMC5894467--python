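# Methods

## Problem and data model

A blood-pressure GWAS yields *index (lead) SNPs*; linkage disequilibrium
(LD) makes nearby variants statistically interchangeable with the lead, so
inference about mechanism must operate on *candidate sets* per locus. The
pipeline joins four evidence layers on those candidates: per-tissue
chromatin peak tracks (cell-type specificity), chromatin-interaction
anchor pairs (variant-to-gene mapping), eQTL tables (expression support)
and druggable-genome/drug–gene tables (translational annotation).

Coordinates follow each format's native convention: BED/BEDPE intervals
are 0-based half-open, variant positions 1-based. The single conversion
point is `intervals.variant_base`, mapping position *p* to `[p−1, p)`;
every overlap test for a variant routes through it. Touching half-open
intervals do not overlap. Gene identity is `gene_id`; symbols are
display-only, so symbol collisions can never distort gene counts.
Duplicate rows in any input table or track are dropped with a logged
count before anything is counted.

## Candidate expansion

Mode `ld` keeps proxies with r² ≥ `r2_min` (default 0.8, the conventional
proxy threshold). Mode `window` keeps pool variants with
|pos − lead_pos| ≤ `window_bp` (closed interval on 1-based positions;
default 50 kb). Default mode `ld_then_window` uses LD when the lead has
proxy rows and the window otherwise, keeping the pipeline runnable when no
reference-panel proxies exist. LD computation itself is out of scope —
proxies arrive precomputed. The locus region spans
`[min candidate pos − 1, max candidate pos)`, extended to at least
lead ± window in window mode. Lowering `r2_min` or raising `window_bp`
can only grow a candidate set; a lead is always its own candidate.

## Functional annotation

Context labels form a partition: *exonic* if the variant base intersects
any exon of any gene, else *intronic* if it intersects any gene body, else
*intergenic*. Exonic dominates intronic under overlapping genes; a
chromosome missing from the annotation yields intergenic with a log note.
Finer classes (UTR, promoter) are deliberately not distinguished. The
deleteriousness filter keeps CADD PHRED **strictly above** 12.37 (the
published deleteriousness cutoff); unscored variants are excluded and
counted separately, never errors.

## Cell-type specificity

The statistic per tissue is the number of loci with at least one candidate
base inside a peak — binary at the locus level, because LD makes SNP-level
counts within a locus dependent; each locus contributes at most 1. A
signal-weighted variant is not implemented; peak signal values are carried
through merging (max) but ignored by the statistic.

The null preserves local architecture: per replicate, each locus's
candidates are shifted together by one uniform integer offset in
±`shift_bp` (default 500 kb; B = 1000), and positions pushed below 1 are
reflected (p → 2 − p). Empirical p-values use the add-one rule
p = (1 + #{null ≥ obs})/(B + 1), so p ≥ 1/(B+1) and is never 0.
Every tissue's null uses the same seed and therefore the same offsets:
identical tracks receive identical p-values, results cannot depend on
input order, and the same seed reproduces the same null vector bit-for-bit
(single numpy PCG64 generator). Tissues are ranked by ascending p, ties
broken by descending fold (observed / null mean, the mean floored at 1e−6
to stay finite on empty nulls) then tissue id; Benjamini–Hochberg q-values
are computed across tissues. Ranks are invariant to the correction choice.

Calibration: permutation p-values are discrete. When the hit count takes
only a handful of values (sparse tracks, few loci), the p-value lattice is
coarse and a Kolmogorov–Smirnov comparison against the *continuous*
uniform measures the lattice, not the calibration. The calibration
experiment in the test suite therefore uses a non-degenerate design —
100 loci and ~20% track coverage, giving a per-locus null hit rate near
0.4 and a fine lattice — under which the 50-tissue p-value set passes the
KS 1% criterion and the ≤0.05 tail stays within binomial 99% bounds.

## Variant-to-gene mapping

The promoter window is strand-aware around the TSS: `[tss0−up, tss0+down)`
for `+` genes (tss0 = tss − 1) and `[tss−down, tss+up)` for `−` genes,
clipped at 0; defaults up = 2000, down = 500 — a conventional promoter
definition, configurable. A link (variant, gene, tissue) requires an
interaction pair with the variant base in one anchor and the promoter
overlapping the *other*; both orientations are checked, so anchor order is
irrelevant. Co-occurrence in the same anchor is not evidence and produces
no link, and a SNP inside a promoter with no interaction is likewise not
mapped here — keeping the interaction-mapped gene set cleanly defined so
the tier arithmetic below is well-posed. Trans-chromosomal pairs are
excluded by default (cis-dominated assays); a minimum interaction score
filter is available per run. Links deduplicate on (variant, gene, tissue),
keeping the first supporting pair index for provenance.

## eQTL integration and tiers

Candidate eQTLs qualify at q ≤ `q_max` (default 0.05, boundary inclusive);
records without q-values fall back to their significance flag. "Relevant
tissues" is a configurable whitelist, not a hard-coded list; by default
all tissues qualify, and Hi-C and eQTL support may come from different
tissues (an any-tissue reading; a same-tissue restriction can be imposed
by whitelisting). Per gene, tissues and supporting variants are set
unions; the tier is BOTH / HIC_ONLY / EQTL_ONLY according to which sources
are non-empty. Counts satisfy `n_total = n_hic + n_added` and
`n_confirmed ≤ n_hic` identically — these are invariants of the
definition, fuzz-tested, not empirical observations.

## Druggability and summary

Tiers join on gene_id (NONE when absent). The antihypertensive flag is an
ATC-prefix test, default {C02, C03, C07, C08, C09} (antihypertensives,
diuretics, beta blockers, calcium-channel blockers, renin–angiotensin
agents), overridable. A gene is inside the associated loci iff its body
intersects any locus region (half-open); a gene overlapping two loci
counts once; genes without models are "unknown" and
inside + outside + unknown = total. The summary is a pure function of the
annotated evidence.

## Synthetic-data generator

`simulate_bundle` emulates the joint structure the pipeline consumes: a
toy genome (2 × 10 Mb), 300 non-overlapping genes with exons, 40 loci with
Poisson(5) proxies within ±25 kb (r² ~ U(0.4, 1), candidates at r² ≥ 0.8),
8 tissues of which 2 carry planted enrichment (a peak dropped on one
candidate in 70% of loci) over 200 background 2-kb peaks per tissue,
30 planted interaction target genes, a 0.3 confirmed fraction echoed as
q = 0.01 eQTLs, 10 eQTL-only genes, 30 background eQTL records on
non-candidate variants, a 98/905 deleterious CADD fraction among leads,
druggable tier fractions 10/6/5% and antihypertensive drugs on ~15% of
mapped druggable genes. Scale and plant strengths are desk-scale choices:
the whole bundle generates and analyses in seconds.

Planted interaction anchors are constructed so recovery is exact when
background rates are zero: the SNP-side anchor (≤ ±1 kb) is truncated to
exclude every other candidate and is kept ≥ 1.5 kb from any promoter
window; the gene-side anchor is the promoter window itself, and genes are
spaced ≥ 10 kb so promoter windows never overlap. Background interaction
and eQTL rates default to 0 so the stored `expected_counts` are exact;
raising them can add false links (precision ≤ 1) but never remove planted
ones (recall stays 1). The generator self-checks that `expected_counts`
follows from the planted links by the same tier arithmetic the pipeline
uses, and all randomness flows from one seeded generator: same seed,
byte-identical bundle.

`simulate_gwas_catalog` generates an index-variant table with prescribed
marginal counts — 905 variants, 84 exonic, 98 with CADD strictly above
12.37 by default, i.e. a 90.7% noncoding share — by placing variants into
exons / gene bodies / intergenic space by rejection sampling. The split of
noncoding variants into intronic vs intergenic (45/55) is a free choice;
only the combined share is structural.

What the generator does **not** emulate: population-genetic LD (proxy r²
values are i.i.d., not distance-decaying), Hi-C distance decay and
contact-frequency noise, peak signal profiles, genome build idiosyncrasies.
Passing planted-truth tests therefore demonstrates correctness of the
pipeline's arithmetic and geometry on well-formed inputs, not robustness
to real-data artifacts such as build mismatches or symbol-keyed joins.

## Numerical and degenerate-input choices

Null summary uses the sample SD (ddof = 1; 0 when B = 1). Empty tables are
empty results with a warning, not errors. Unresolvable candidate IDs in
hit counting are hard errors naming the ID. Infeasible generator
parameters fail before any file is written. Output writers sort rows on
documented keys and format floats via `repr`, so identical inputs yield
byte-identical files and written tables round-trip exactly.

## Known limitations

- The expansion rule producing a published candidate count from a given
  lead table depends on the proxy panel used; with user-supplied proxy
  tables the run manifest (log) states the rule and counts actually used.
- The enrichment statistic and shift null are one defensible choice among
  several (e.g. matched-SNP resampling); ranks under saturating or
  near-empty tracks are dominated by ties and should not be interpreted.
- Study-scale headline counts require the original external resources
  (real Hi-C panels, GTEx, druggable-genome tables) and are not
  reproducible from synthetic data; the package reproduces the arithmetic
  and geometry that generate them.
- No liftover, no VCF parsing, no colocalization statistics, no LD
  computation from genotype panels.
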