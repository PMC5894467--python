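"""Genomic-context classification and the CADD deleteriousness filter.

Most trait-associated index variants fall outside coding sequence; this
module recomputes that picture for any variant table: each variant gets
exactly one label from {exonic, intronic, intergenic} (exonic dominates
intronic when genes overlap), and a CADD PHRED threshold filter separates
the small predicted-deleterious minority.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import variant_base
from .model import GeneModel, Variant

log = logging.getLogger(__name__)

__all__ = ["GeneIndex", "classify_variant", "annotate_contexts", "filter_deleterious",
           "CADD_DELETERIOUS_THRESHOLD"]

# PHRED-scaled CADD score above which a variant is treated as deleterious
CADD_DELETERIOUS_THRESHOLD = 12.37


class GeneIndex:
    """Interval lookup over gene bodies and exons, per chromosome."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._bodies: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        for g in genes:
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(
                g.body.start, g.body.end, g.gene_id
            )
            for ex in g.exons:
                self._exons.setdefault(g.chrom, IntervalTree()).addi(
                    ex.start, ex.end, g.gene_id
                )

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._bodies

    def in_exon(self, chrom: str, pos0: int) -> bool:
        tree = self._exons.get(chrom)
        return bool(tree and tree.overlaps_point(pos0))

    def in_body(self, chrom: str, pos0: int) -> bool:
        tree = self._bodies.get(chrom)
        return bool(tree and tree.overlaps_point(pos0))


def classify_variant(v: Variant, index: GeneIndex) -> str:
    """Label a variant exonic / intronic / intergenic.

    Exonic if its base intersects any exon of any gene; else intronic if it
    intersects any gene body; else intergenic.  A chromosome absent from the
    annotation yields intergenic (with a logged note).
    """
    base = variant_base(v.chrom, v.pos)
    if not index.has_chrom(v.chrom):
        log.info("variant %s on chrom %s absent from gene annotation", v.variant_id, v.chrom)
        return "intergenic"
    if index.in_exon(v.chrom, base.start):
        return "exonic"
    if index.in_body(v.chrom, base.start):
        return "intronic"
    return "intergenic"


def annotate_contexts(
    variants: Sequence[Variant], genes: Sequence[GeneModel]
) -> Counter:
    """Classify every variant in place; returns context counts.

    The labels partition the input: counts sum to ``len(variants)``.
    """
    index = GeneIndex(genes)
    counts: Counter = Counter()
    for v in variants:
        v.context = classify_variant(v, index)
        counts[v.context] += 1
    return counts


def noncoding_fraction(counts: Counter) -> float:
    """Fraction of variants labelled intronic or intergenic."""
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return (counts["intronic"] + counts["intergenic"]) / total


def filter_deleterious(
    variants: Sequence[Variant],
    threshold: float = CADD_DELETERIOUS_THRESHOLD,
) -> list[Variant]:
    """Keep variants with a CADD PHRED score strictly above ``threshold``.

    Variants without a score are excluded and counted separately (logged),
    never errors: supplementary score tables rarely cover every variant.
    """
    if not (threshold == threshold and abs(threshold) != float("inf")):
        raise ValueError("threshold must be finite")
    kept = [v for v in variants if v.cadd_phred is not None and v.cadd_phred > threshold]
    n_unscored = sum(v.cadd_phred is None for v in variants)
    if n_unscored:
        log.info("%d variants lack a CADD score and were excluded", n_unscored)
    return kept


def attach_cadd(
    variants: Sequence[Variant], scores: Iterable[tuple[str, Optional[float]]]
) -> int:
    """Join a (variant_id, cadd_phred) table onto variants; returns n matched."""
    table = {vid: s for vid, s in scores}
    n = 0
    for v in variants:
        if v.variant_id in table and table[v.variant_id] is not None:
            v.cadd_phred = table[v.variant_id]
            n += 1
    return n
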