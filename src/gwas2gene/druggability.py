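"""Druggability annotation and the end-of-pipeline summary.

Evidence genes are joined to a druggable-genome tier table and a drug-gene
interaction table; a gene is flagged antihypertensive-interacting when any
of its drugs carries an ATC code in the configured prefixes (default
C02/C03/C07/C08/C09 — the common antihypertensive classes).  Genes are also
classified as physically inside or outside the associated loci, and all
headline counts are collected into one summary record.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .eqtl import TierCounts
from .model import (
    DrugGeneRecord,
    DruggabilityRecord,
    GeneEvidence,
    GeneModel,
    Locus,
)

log = logging.getLogger(__name__)

__all__ = [
    "ATC_ANTIHYPERTENSIVE_PREFIXES",
    "annotate_druggability",
    "classify_gene_position",
    "summarize_counts",
    "Summary",
]

ATC_ANTIHYPERTENSIVE_PREFIXES = ("C02", "C03", "C07", "C08", "C09")


def annotate_druggability(
    evidence: Sequence[GeneEvidence],
    druggable: Sequence[DruggabilityRecord],
    drug_gene: Sequence[DrugGeneRecord] = (),
    atc_prefixes: Iterable[str] = ATC_ANTIHYPERTENSIVE_PREFIXES,
) -> list[GeneEvidence]:
    """Attach tiers and drugs to evidence genes, in place; returns the list.

    Genes absent from the druggable table get tier NONE; the
    antihypertensive flag is set iff any attached drug's ATC code starts
    with a configured prefix.
    """
    prefixes = tuple(atc_prefixes)
    tiers = {r.gene_id: r.tier for r in druggable}
    drugs: dict[str, list[tuple[str, Optional[str]]]] = {}
    for rec in drug_gene:
        drugs.setdefault(rec.gene_id, []).append((rec.drug_name, rec.atc_code))
    for ev in evidence:
        ev.druggability = DruggabilityRecord(
            gene_id=ev.gene_id,
            tier=tiers.get(ev.gene_id, "NONE"),
            drugs=sorted(drugs.get(ev.gene_id, [])),
        )
        ev.antihypertensive = any(
            atc is not None and atc.startswith(prefixes)
            for _, atc in ev.druggability.drugs
        )
    n_druggable = sum(ev.druggability.tier != "NONE" for ev in evidence)
    n_anti = sum(ev.antihypertensive for ev in evidence)
    log.info("druggability: %d druggable genes, %d antihypertensive-interacting",
             n_druggable, n_anti)
    return list(evidence)


def classify_gene_position(
    evidence: Sequence[GeneEvidence],
    loci: Sequence[Locus],
    genes: Sequence[GeneModel],
) -> list[GeneEvidence]:
    """Set inside_locus per gene: does the gene body intersect any locus region?

    Half-open semantics: touching intervals do not intersect.  Genes missing
    from the annotation stay unknown (None), with a log line.
    """
    regions: dict[str, IntervalTree] = {}
    for locus in loci:
        regions.setdefault(locus.region.chrom, IntervalTree()).addi(
            locus.region.start, locus.region.end
        )
    bodies = {g.gene_id: g for g in genes}
    n_unknown = 0
    for ev in evidence:
        g = bodies.get(ev.gene_id)
        if g is None:
            ev.inside_locus = None
            n_unknown += 1
            continue
        tree = regions.get(g.chrom)
        ev.inside_locus = bool(tree and tree.overlap(g.body.start, g.body.end))
    if n_unknown:
        log.info("%d evidence genes have no gene model; position unknown", n_unknown)
    return list(evidence)


@dataclass(frozen=True)
class Summary:
    """Headline counts of one pipeline run (the flow-diagram numbers)."""

    n_candidates: int
    n_hic_genes: int
    n_confirmed: int
    n_added: int
    n_total: int
    n_druggable: int
    n_antihypertensive: int
    n_inside_loci: int
    n_outside_loci: int
    n_unknown_position: int

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def summarize_counts(
    evidence: Sequence[GeneEvidence],
    tier_counts: Optional[TierCounts] = None,
    n_candidates: int = 0,
) -> Summary:
    """Collapse annotated evidence into one summary row.

    A pure function of its inputs: recomputation on the same evidence gives
    the same record.  ``tier_counts`` defaults to a recount from the tiers.
    """
    if tier_counts is None:
        tier_counts = TierCounts(
            n_hic=sum(e.tier in ("HIC_ONLY", "BOTH") for e in evidence),
            n_confirmed=sum(e.tier == "BOTH" for e in evidence),
            n_added=sum(e.tier == "EQTL_ONLY" for e in evidence),
        )
    summary = Summary(
        n_candidates=n_candidates,
        n_hic_genes=tier_counts.n_hic,
        n_confirmed=tier_counts.n_confirmed,
        n_added=tier_counts.n_added,
        n_total=tier_counts.n_total,
        n_druggable=sum(
            e.druggability is not None and e.druggability.tier != "NONE"
            for e in evidence
        ),
        n_antihypertensive=sum(e.antihypertensive for e in evidence),
        n_inside_loci=sum(e.inside_locus is True for e in evidence),
        n_outside_loci=sum(e.inside_locus is False for e in evidence),
        n_unknown_position=sum(e.inside_locus is None for e in evidence),
    )
    log.info(
        "summary: %d candidates -> %d Hi-C genes (+%d eQTL-only) = %d genes; "
        "%d druggable, %d antihypertensive-interacting, %d outside loci",
        summary.n_candidates, summary.n_hic_genes, summary.n_added,
        summary.n_total, summary.n_druggable, summary.n_antihypertensive,
        summary.n_outside_loci,
    )
    return summary
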