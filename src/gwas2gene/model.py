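"""In-memory data model for the variant-to-gene pipeline.

One set of typed records is shared by every stage: variants and loci on the
GWAS side; peak tracks, interaction pairs and gene models on the epigenome
side; eQTL, druggability and evidence records on the integration side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import BaseLookup, GenomicInterval, merge_peaks

TRAITS = frozenset({"SBP", "DBP", "PP", "HTN", "NA"})
ROLES = frozenset({"lead", "proxy"})
CONTEXTS = frozenset({"exonic", "intronic", "intergenic", "unknown"})
TIERS = frozenset({"TIER1", "TIER2", "TIER3", "NONE"})


@dataclass
class Variant:
    """An index (lead) or LD-proxy SNP.

    ``pos`` is 1-based.  ``lead_id`` is empty iff ``role == "lead"``;
    ``ld_r2`` is the squared correlation with the lead for proxies.
    """

    variant_id: str
    chrom: str
    pos: int
    trait: str = "NA"
    role: str = "lead"
    lead_id: str = ""
    ld_r2: Optional[float] = None
    cadd_phred: Optional[float] = None
    context: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.trait not in TRAITS:
            raise ValueError(f"{self.variant_id}: unknown trait {self.trait!r}")
        if self.role not in ROLES:
            raise ValueError(f"{self.variant_id}: unknown role {self.role!r}")
        if (self.role == "lead") != (self.lead_id == ""):
            raise ValueError(
                f"{self.variant_id}: lead_id must be empty iff role is 'lead'"
            )
        if self.ld_r2 is not None and not (0.0 <= self.ld_r2 <= 1.0):
            raise ValueError(f"{self.variant_id}: ld_r2 outside [0, 1]: {self.ld_r2}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"{self.variant_id}: negative CADD score")
        if self.context not in CONTEXTS:
            raise ValueError(f"{self.variant_id}: unknown context {self.context!r}")


class PeakTrack:
    """A per-tissue track of (merged, sorted) peaks for one chromatin mark."""

    def __init__(
        self,
        tissue_id: str,
        mark: str,
        peaks: Sequence[tuple[GenomicInterval, Optional[float]]],
    ):
        self.tissue_id = tissue_id
        self.mark = mark
        self.peaks: list[tuple[GenomicInterval, Optional[float]]] = merge_peaks(peaks)
        self._lookup = BaseLookup([iv for iv, _ in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.peaks]

    def hit_base(self, chrom: str, pos0) -> np.ndarray:
        """Vectorised: does each 0-based position fall inside a peak?"""
        return self._lookup.hit(chrom, pos0)


@dataclass
class InteractionPair:
    """One chromatin-interaction (e.g. Hi-C) contact in one tissue."""

    tissue_id: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: Optional[float] = None

    @property
    def is_trans(self) -> bool:
        return self.anchor_a.chrom != self.anchor_b.chrom


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int  # 1-based
    body: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (self.body.start <= self.tss - 1 < self.body.end):
            raise ValueError(f"{self.gene_id}: TSS outside gene body")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(f"{self.gene_id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = ex.end


@dataclass
class EqtlRecord:
    variant_id: str
    gene_id: str
    tissue_id: str
    effect: float
    qvalue: Optional[float] = None
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(
                f"eQTL {self.variant_id}/{self.gene_id}: qvalue outside [0, 1]"
            )


@dataclass
class DruggabilityRecord:
    gene_id: str
    tier: str = "NONE"
    drugs: list[tuple[str, Optional[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"{self.gene_id}: unknown druggability tier {self.tier!r}")


@dataclass
class DrugGeneRecord:
    gene_id: str
    drug_name: str
    atc_code: Optional[str] = None


@dataclass
class Locus:
    """A lead SNP with its candidate-SNP set and spanned genomic region."""

    lead_id: str
    region: GenomicInterval
    candidate_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.lead_id not in self.candidate_ids:
            raise ValueError(f"locus {self.lead_id}: lead missing from candidates")


@dataclass
class V2GLink:
    """A variant-to-gene link supported by a chromatin interaction."""

    variant_id: str
    gene_id: str
    tissue_id: str
    source: str = "interaction"
    interaction_index: int = -1


@dataclass
class TissueEnrichment:
    tissue_id: str
    observed_hits: int
    null_mean: float
    null_sd: float
    fold: float
    p_emp: float
    q_bh: float
    rank: int


@dataclass
class GeneEvidence:
    """Per-gene integration record: which sources support it, and how."""

    gene_id: str
    interaction_tissues: set[str] = field(default_factory=set)
    eqtl_tissues: set[str] = field(default_factory=set)
    tier: str = ""
    supporting_variants: set[str] = field(default_factory=set)
    inside_locus: Optional[bool] = None
    druggability: Optional[DruggabilityRecord] = None
    antihypertensive: bool = False

    def assign_tier(self) -> None:
        has_hic = bool(self.interaction_tissues)
        has_eqtl = bool(self.eqtl_tissues)
        if has_hic and has_eqtl:
            self.tier = "BOTH"
        elif has_hic:
            self.tier = "HIC_ONLY"
        elif has_eqtl:
            self.tier = "EQTL_ONLY"
        else:
            raise ValueError(f"{self.gene_id}: evidence record with no support")
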