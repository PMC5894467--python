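"""Expand lead SNPs into loci with candidate-SNP sets.

A GWAS index variant tags a region, not a causal base: linkage
disequilibrium (LD) means tens of nearby SNPs are statistically
interchangeable with the lead.  Each lead is therefore expanded into a
candidate set, either from a precomputed LD-proxy table (r-squared
threshold) or, when no panel-derived proxies exist, by a fixed physical
window around the lead.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional, Sequence

from .intervals import GenomicInterval
from .model import Locus, Variant

log = logging.getLogger(__name__)

__all__ = ["expand_lead", "build_candidates"]

DEFAULT_R2_MIN = 0.8
DEFAULT_WINDOW_BP = 50_000
MODES = ("ld", "window", "ld_then_window")


def _window_members(lead: Variant, pool: Sequence[Variant], window_bp: int) -> list[Variant]:
    # closed interval |pos - lead_pos| <= window_bp on 1-based positions
    return [
        v
        for v in pool
        if v.chrom == lead.chrom
        and abs(v.pos - lead.pos) <= window_bp
        and v.variant_id != lead.variant_id
    ]


def expand_lead(
    lead: Variant,
    mode: str = "ld_then_window",
    proxies: Sequence[Variant] = (),
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
    pool: Optional[Sequence[Variant]] = None,
) -> tuple[Locus, dict[str, Variant]]:
    """Expand one lead into a locus.

    ``proxies`` are this lead's proxy records (role=proxy, carrying ld_r2);
    ``pool`` is the variant pool searched in window mode (defaults to the
    proxies themselves, ignoring r2).  Returns the locus plus the id->Variant
    map of its members.

    Modes: ``ld`` keeps proxies with ld_r2 >= r2_min; ``window`` keeps pool
    variants within +/- window_bp of the lead (closed interval, 1-based);
    ``ld_then_window`` uses LD when the lead has any proxy rows and falls
    back to the window otherwise.
    """
    if mode not in MODES:
        raise ValueError(f"unknown expansion mode {mode!r}")
    if not (0.0 <= r2_min <= 1.0):
        raise ValueError(f"r2_min outside [0, 1]: {r2_min}")
    if window_bp < 0:
        raise ValueError(f"negative window_bp: {window_bp}")

    proxies = list(proxies)
    use_mode = mode
    if mode == "ld_then_window":
        use_mode = "ld" if proxies else "window"

    members: dict[str, Variant] = {lead.variant_id: lead}
    floor_start: Optional[int] = None
    ceil_end: Optional[int] = None
    if use_mode == "ld":
        if not proxies:
            log.warning(
                "lead %s absent from proxy table; locus contains only the lead",
                lead.variant_id,
            )
        for p in proxies:
            if p.ld_r2 is not None and p.ld_r2 >= r2_min:
                members[p.variant_id] = p
    else:
        search = list(pool) if pool is not None else proxies
        for v in _window_members(lead, search, window_bp):
            members[v.variant_id] = v
        floor_start = max(0, lead.pos - 1 - window_bp)
        ceil_end = lead.pos + window_bp

    positions = [v.pos for v in members.values()]
    start = min(positions) - 1
    end = max(positions)
    if floor_start is not None:
        start = min(start, floor_start)
        end = max(end, ceil_end)
    locus = Locus(
        lead_id=lead.variant_id,
        region=GenomicInterval(lead.chrom, start, end),
        candidate_ids=frozenset(members),
    )
    return locus, members


def build_candidates(
    leads: Sequence[Variant],
    proxies: Sequence[Variant] = (),
    mode: str = "ld_then_window",
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
    pool: Optional[Sequence[Variant]] = None,
) -> tuple[list[Locus], dict[str, Variant]]:
    """Expand every lead; returns (loci, global candidate index).

    The global index is the union over loci (a variant shared by two loci is
    counted once globally but retained in both loci).  Duplicate lead IDs are
    an error; proxies whose lead_id matches no lead are ignored with a log.
    """
    seen: set[str] = set()
    dupes = sorted({l.variant_id for l in leads if l.variant_id in seen or seen.add(l.variant_id)})
    if dupes:
        raise ValueError(f"duplicate lead IDs: {', '.join(dupes)}")

    by_lead: dict[str, list[Variant]] = defaultdict(list)
    orphans = 0
    lead_ids = {l.variant_id for l in leads}
    for p in proxies:
        if p.lead_id in lead_ids:
            by_lead[p.lead_id].append(p)
        else:
            orphans += 1
    if orphans:
        log.info("ignored %d proxy rows whose lead is not in the lead table", orphans)

    loci: list[Locus] = []
    index: dict[str, Variant] = {}
    for lead in leads:
        locus, members = expand_lead(
            lead,
            mode=mode,
            proxies=by_lead.get(lead.variant_id, ()),
            r2_min=r2_min,
            window_bp=window_bp,
            pool=pool,
        )
        loci.append(locus)
        index.update(members)
    log.info("expanded %d leads into %d candidate SNPs", len(leads), len(index))
    return loci, index
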