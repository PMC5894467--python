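"""Variant-to-gene mapping through chromatin-interaction pairs.

A candidate SNP is linked to a gene when some interaction pair (Hi-C /
promoter-capture contact) has the SNP's base in one anchor and the gene's
promoter window overlapping the *other* anchor — in either orientation.
Proximity alone never creates a link here: a SNP sitting inside a promoter
with no interaction evidence is not mapped by this stage.
"""

from __future__ import annotations

import bisect
import logging
from typing import Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval
from .model import GeneModel, InteractionPair, V2GLink, Variant

log = logging.getLogger(__name__)

__all__ = ["promoter_interval", "map_candidates_to_genes"]

DEFAULT_PROMOTER_UP = 2_000
DEFAULT_PROMOTER_DOWN = 500


def promoter_interval(
    g: GeneModel,
    up_bp: int = DEFAULT_PROMOTER_UP,
    down_bp: int = DEFAULT_PROMOTER_DOWN,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at 0.

    For '+' genes the window is ``[tss0 - up, tss0 + down)`` with
    ``tss0 = tss - 1`` (0-based TSS); for '-' genes upstream runs toward
    higher coordinates, giving ``[tss - down, tss + up)``.
    """
    if up_bp < 0 or down_bp < 0:
        raise ValueError("promoter window sizes must be >= 0")
    if up_bp == 0 and down_bp == 0:
        raise ValueError("promoter window cannot be empty")
    if g.strand == "+":
        start, end = g.tss - 1 - up_bp, g.tss - 1 + down_bp
    else:
        start, end = g.tss - down_bp, g.tss + up_bp
    return GenomicInterval(g.chrom, max(0, start), end)


class _VariantIndex:
    """Per-chromosome sorted positions for range queries over candidates."""

    def __init__(self, candidates: Mapping[str, Variant]):
        self._pos: dict[str, list[int]] = {}
        self._ids: dict[str, list[str]] = {}
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for vid, v in candidates.items():
            by_chrom.setdefault(v.chrom, []).append((v.pos, vid))
        for chrom, items in by_chrom.items():
            items.sort()
            self._pos[chrom] = [p for p, _ in items]
            self._ids[chrom] = [i for _, i in items]

    def in_interval(self, iv: GenomicInterval) -> list[str]:
        """Candidate IDs whose base [pos-1, pos) lies inside the interval."""
        pos = self._pos.get(iv.chrom)
        if pos is None:
            return []
        # base inside iv  <=>  iv.start <= pos - 1 < iv.end
        lo = bisect.bisect_left(pos, iv.start + 1)
        hi = bisect.bisect_right(pos, iv.end)
        return self._ids[iv.chrom][lo:hi]


def map_candidates_to_genes(
    candidates: Mapping[str, Variant],
    interactions: Sequence[InteractionPair],
    genes: Sequence[GeneModel],
    up_bp: int = DEFAULT_PROMOTER_UP,
    down_bp: int = DEFAULT_PROMOTER_DOWN,
    include_trans: bool = False,
    min_score: Optional[float] = None,
) -> list[V2GLink]:
    """Emit deduplicated (variant, gene, tissue) links from interaction pairs.

    A link requires the variant base in one anchor and the gene's promoter
    overlapping the partner anchor; both orientations are checked, so the
    result is invariant under anchor swaps.  Trans pairs are skipped unless
    ``include_trans``; pairs scoring below ``min_score`` are skipped when a
    score filter is set.  ``interaction_index`` records the first pair (by
    input order) supporting each link.
    """
    promoters: dict[str, IntervalTree] = {}
    for g in genes:
        win = promoter_interval(g, up_bp, down_bp)
        promoters.setdefault(g.chrom, IntervalTree()).addi(win.start, win.end, g.gene_id)
    vindex = _VariantIndex(candidates)

    links: dict[tuple[str, str, str], V2GLink] = {}
    n_trans = 0
    for idx, pair in enumerate(interactions):
        if pair.is_trans and not include_trans:
            n_trans += 1
            continue
        if min_score is not None and (pair.score is None or pair.score < min_score):
            continue
        for snp_anchor, gene_anchor in (
            (pair.anchor_a, pair.anchor_b),
            (pair.anchor_b, pair.anchor_a),
        ):
            vids = vindex.in_interval(snp_anchor)
            if not vids:
                continue
            tree = promoters.get(gene_anchor.chrom)
            if not tree:
                continue
            gids = {hit.data for hit in tree.overlap(gene_anchor.start, gene_anchor.end)}
            for vid in vids:
                for gid in gids:
                    key = (vid, gid, pair.tissue_id)
                    if key not in links:
                        links[key] = V2GLink(vid, gid, pair.tissue_id,
                                             interaction_index=idx)
    if n_trans:
        log.info("skipped %d trans interaction pairs", n_trans)
    out = sorted(links.values(), key=lambda l: (l.gene_id, l.variant_id, l.tissue_id))
    log.info(
        "mapped %d links: %d distinct genes, %d distinct variants",
        len(out), len({l.gene_id for l in out}), len({l.variant_id for l in out}),
    )
    return out
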