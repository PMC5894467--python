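"""End-to-end orchestration over a bundle directory.

A bundle is a directory with the layout the synthetic generator writes
(and which real supplementary tables can be coerced into): ``loci.tsv``,
``proxies.tsv``, ``genes.tsv``, ``eqtl.tsv``, ``cadd.tsv``,
``druggable.tsv``, ``drug_gene.tsv``, ``tracks/<tissue>.<mark>.bed``,
``interactions/<tissue>.bedpe`` and a ``config.yaml``.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import io as gio
from .annotation import annotate_contexts, attach_cadd, filter_deleterious
from .config import PipelineConfig
from .druggability import (
    Summary,
    annotate_druggability,
    classify_gene_position,
    summarize_counts,
)
from .eqtl import TierCounts, eqtl_gene_links, integrate_evidence
from .expansion import build_candidates
from .model import GeneEvidence, GeneModel, Locus, TissueEnrichment, V2GLink, Variant
from .specificity import rank_tissues
from .v2g import map_candidates_to_genes

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_bundle"]


@dataclass
class PipelineResult:
    loci: list[Locus]
    candidates: dict[str, Variant]
    genes: list[GeneModel]
    context_counts: dict[str, int]
    deleterious: list[Variant]
    links: list[V2GLink]
    eqtl_links: set[tuple[str, str, str]]
    evidence: list[GeneEvidence]
    tier_counts: TierCounts
    summary: Summary
    enrichment: Optional[list[TissueEnrichment]] = None


def run_bundle(
    bundle_dir,
    config: Optional[PipelineConfig] = None,
    run_specificity: bool = False,
) -> PipelineResult:
    """Run expansion, annotation, mapping, integration and reporting.

    The tissue-specificity permutation stage is optional (it is the slow
    step); everything else always runs.
    """
    if config is None:
        cfg_path = os.path.join(bundle_dir, "config.yaml")
        config = PipelineConfig.from_yaml(cfg_path) if os.path.exists(cfg_path) \
            else PipelineConfig()

    leads = gio.read_table(os.path.join(bundle_dir, "loci.tsv"), "loci")
    proxies_path = os.path.join(bundle_dir, "proxies.tsv")
    proxies = gio.read_table(proxies_path, "proxies") if os.path.exists(proxies_path) else []
    genes = gio.read_gene_table(os.path.join(bundle_dir, "genes.tsv"))

    cadd_path = os.path.join(bundle_dir, "cadd.tsv")
    if os.path.exists(cadd_path):
        attach_cadd(leads, gio.read_table(cadd_path, "cadd"))
    context_counts = dict(annotate_contexts(leads, genes))
    deleterious = filter_deleterious(leads, config.cadd_threshold)

    loci, candidates = build_candidates(
        leads, proxies, mode=config.mode, r2_min=config.r2_min,
        window_bp=config.window_bp,
    )

    interactions = []
    for path in sorted(glob.glob(os.path.join(bundle_dir, "interactions", "*.bedpe"))):
        tissue = os.path.basename(path).split(".")[0]
        interactions.extend(gio.read_bedpe(path, tissue))
    links = map_candidates_to_genes(
        candidates, interactions, genes,
        up_bp=config.promoter_up, down_bp=config.promoter_down,
        include_trans=config.include_trans, min_score=config.min_interaction_score,
    )

    eqtl_path = os.path.join(bundle_dir, "eqtl.tsv")
    eqtls = gio.read_table(eqtl_path, "eqtl") if os.path.exists(eqtl_path) else []
    eq_links = eqtl_gene_links(candidates, eqtls, q_max=config.q_max,
                               tissues=config.tissues)
    evidence, tier_counts = integrate_evidence(links, eq_links)

    drug_path = os.path.join(bundle_dir, "druggable.tsv")
    druggable = gio.read_table(drug_path, "druggable") if os.path.exists(drug_path) else []
    dg_path = os.path.join(bundle_dir, "drug_gene.tsv")
    drug_gene = gio.read_table(dg_path, "drug_gene") if os.path.exists(dg_path) else []
    annotate_druggability(evidence, druggable, drug_gene,
                          atc_prefixes=config.atc_prefixes)
    classify_gene_position(evidence, loci, genes)
    summary = summarize_counts(evidence, tier_counts, n_candidates=len(candidates))

    enrichment = None
    if run_specificity:
        tracks = []
        for path in sorted(glob.glob(os.path.join(bundle_dir, "tracks", "*.bed"))):
            name = os.path.basename(path).split(".")
            tracks.append(gio.read_bed(path, name[0], name[1] if len(name) > 2 else "NA"))
        if tracks:
            enrichment = rank_tissues(
                loci, candidates, tracks, B=config.B,
                shift_bp=config.shift_bp, seed=config.seed,
            )

    return PipelineResult(
        loci=loci, candidates=candidates, genes=genes,
        context_counts=context_counts, deleterious=deleterious,
        links=links, eqtl_links=eq_links, evidence=evidence,
        tier_counts=tier_counts, summary=summary, enrichment=enrichment,
    )
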