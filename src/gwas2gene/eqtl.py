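"""eQTL evidence and its integration with interaction-based mapping.

Candidate SNPs that are significant eQTLs tie loci to genes through
expression; combining those ties with the chromatin-interaction links
yields per-gene evidence tiers: interaction-only, eQTL-only ("added"), or
both ("confirmed").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import EqtlRecord, GeneEvidence, V2GLink, Variant

log = logging.getLogger(__name__)

__all__ = ["eqtl_gene_links", "integrate_evidence", "TierCounts"]

DEFAULT_Q_MAX = 0.05


@dataclass(frozen=True)
class TierCounts:
    """Headline gene counts of the integration stage.

    n_hic counts every interaction-mapped gene (confirmed or not);
    n_confirmed those also carrying eQTL support; n_added the eQTL-only
    genes; n_total = n_hic + n_added always.
    """

    n_hic: int
    n_confirmed: int
    n_added: int

    @property
    def n_total(self) -> int:
        return self.n_hic + self.n_added


def eqtl_gene_links(
    candidates: Mapping[str, Variant],
    eqtls: Sequence[EqtlRecord],
    q_max: float = DEFAULT_Q_MAX,
    tissues: Optional[Iterable[str]] = None,
) -> set[tuple[str, str, str]]:
    """Significant (variant, gene, tissue) eQTL links restricted to candidates.

    A record qualifies when its variant is a candidate, its tissue is in the
    whitelist (when one is given) and its q-value is <= q_max (boundary
    inclusive); when a record carries no q-value its significance flag
    governs.  Non-candidate eQTL variants are counted and logged, never
    errors.
    """
    if not (0.0 < q_max <= 1.0):
        raise ValueError(f"q_max outside (0, 1]: {q_max}")
    allowed = set(tissues) if tissues is not None else None
    links: set[tuple[str, str, str]] = set()
    n_noncandidate = 0
    for rec in eqtls:
        if rec.variant_id not in candidates:
            n_noncandidate += 1
            continue
        if allowed is not None and rec.tissue_id not in allowed:
            continue
        if rec.qvalue is not None:
            ok = rec.qvalue <= q_max
        else:
            ok = bool(rec.significant)
        if ok:
            links.add((rec.variant_id, rec.gene_id, rec.tissue_id))
    if n_noncandidate:
        log.info("%d eQTL records matched no candidate SNP", n_noncandidate)
    return links


def integrate_evidence(
    hic_links: Sequence[V2GLink],
    eqtl_links: Iterable[tuple[str, str, str]],
) -> tuple[list[GeneEvidence], TierCounts]:
    """Merge both link sources into per-gene evidence records plus tier counts.

    Order-invariant and idempotent: tissues and supporting variants are set
    unions, tiers follow from which sets are non-empty.
    """
    by_gene: dict[str, GeneEvidence] = {}

    def get(gid: str) -> GeneEvidence:
        if gid not in by_gene:
            by_gene[gid] = GeneEvidence(gene_id=gid)
        return by_gene[gid]

    for link in hic_links:
        ev = get(link.gene_id)
        ev.interaction_tissues.add(link.tissue_id)
        ev.supporting_variants.add(link.variant_id)
    for vid, gid, tid in eqtl_links:
        ev = get(gid)
        ev.eqtl_tissues.add(tid)
        ev.supporting_variants.add(vid)

    evidence = sorted(by_gene.values(), key=lambda e: e.gene_id)
    for ev in evidence:
        ev.assign_tier()
    counts = TierCounts(
        n_hic=sum(e.tier in ("HIC_ONLY", "BOTH") for e in evidence),
        n_confirmed=sum(e.tier == "BOTH" for e in evidence),
        n_added=sum(e.tier == "EQTL_ONLY" for e in evidence),
    )
    log.info(
        "integration: %d interaction-mapped genes, %d confirmed by eQTL, %d added, %d total",
        counts.n_hic, counts.n_confirmed, counts.n_added, counts.n_total,
    )
    return evidence, counts
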