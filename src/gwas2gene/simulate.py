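"""Synthetic data: a self-consistent toy bundle for every pipeline stage.

Two generators live here.  :func:`simulate_bundle` writes a complete input
bundle — toy genome with genes, GWAS loci with LD proxies, per-tissue peak
tracks with planted enrichment, interaction pairs wiring planted SNPs to
planted target promoters, eQTL records partially echoing those links,
CADD scores and druggability tables — plus a machine-readable truth file,
so planted-link recovery can be checked exactly.
:func:`simulate_gwas_catalog` builds an index-variant table with prescribed
marginal counts (how many variants are coding, how many exceed the CADD
deleteriousness threshold), emulating a published supplementary table whose
headline counts are known.

All randomness flows from one seeded numpy generator; identical parameters
and seed give byte-identical bundles.

What the generator does NOT emulate: population-genetic LD structure
(proxy r-squared values are i.i.d. draws), Hi-C distance decay, and signal
profiles within peaks.  Only the statistical structure the pipeline
consumes is planted.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import io as gio
from .config import PipelineConfig
from .expansion import build_candidates
from .intervals import GenomicInterval
from .model import (
    DrugGeneRecord,
    DruggabilityRecord,
    EqtlRecord,
    GeneModel,
    InteractionPair,
    Locus,
    PeakTrack,
    Variant,
)
from .v2g import promoter_interval

log = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "simulate_bundle",
    "simulate_gwas_catalog",
    "verify_truth_recovery",
    "RecoveryReport",
]

ANTIHYPERTENSIVE_ATC = ("C02AB01", "C03AA03", "C07AB02", "C08CA01", "C09CA04")
OTHER_ATC = ("A10BA02", "J01CA04", "L01XE07", "N02BE01", "R03AC02")


class ParameterError(ValueError):
    """Requested synthetic-genome parameters are infeasible."""


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; the defaults define a desk-scale study.

    Toy scale: 2 chromosomes of 10 Mb, 300 genes, 40 loci, 8 tissues of
    which 2 carry planted enrichment; the whole bundle generates and runs
    end-to-end in seconds.
    """

    n_chrom: int = 2
    chrom_len: int = 10_000_000
    n_genes: int = 300
    gene_len_min: int = 5_000
    gene_len_max: int = 30_000
    min_gene_gap: int = 10_000
    exons_min: int = 2
    exons_max: int = 6
    # loci
    n_loci: int = 40
    proxies_mean: float = 5.0  # Poisson mean per lead
    proxy_span: int = 25_000  # proxies within +/- span of the lead
    r2_min: float = 0.8  # candidate definition used for the plant
    # tissues / peaks
    n_tissues: int = 8
    n_enriched: int = 2
    enriched_hit_frac: float = 0.7  # fraction of loci given a planted peak
    background_peaks: int = 200  # per tissue, genome-wide
    peak_width: int = 2_000
    # interactions
    n_hic_genes: int = 30
    background_interactions: int = 0  # random cis pairs per tissue
    background_anchor_width: int = 5_000
    promoter_up: int = 2_000
    promoter_down: int = 500
    promoter_margin: int = 1_500  # planted SNPs stay this far from promoters
    # eQTLs
    confirmed_frac: float = 0.3  # Hi-C genes echoed as eQTLs
    n_eqtl_only_genes: int = 10
    background_eqtls: int = 30  # non-candidate records
    eqtl_q_planted: float = 0.01
    # scores & druggability
    frac_deleterious: float = 98 / 905
    druggable_fracs: tuple[tuple[str, float], ...] = (
        ("TIER1", 0.10), ("TIER2", 0.06), ("TIER3", 0.05),
    )
    antihypertensive_frac: float = 0.15  # of mapped druggable genes


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated bundle."""

    seed: int
    params: dict
    candidate_ids: list[str]
    enriched_tissues: dict[str, int]  # tissue -> planted hit count
    planted_interaction_links: list[tuple[str, str, str]]
    planted_eqtl_links: list[tuple[str, str, str]]
    confirmed_genes: list[str]
    expected_counts: dict[str, int]
    n_deleterious_leads: int

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, "rt", encoding="utf-8") as fh:
            data = json.load(fh)
        data["planted_interaction_links"] = [tuple(t) for t in data["planted_interaction_links"]]
        data["planted_eqtl_links"] = [tuple(t) for t in data["planted_eqtl_links"]]
        if "druggable_fracs" in data["params"]:  # JSON has no tuples
            data["params"]["druggable_fracs"] = tuple(
                tuple(x) for x in data["params"]["druggable_fracs"]
            )
        return cls(**data)


def _place_genes(rng: np.random.Generator, params: SimParams) -> list[GeneModel]:
    """Non-overlapping genes with exons, spread over the toy chromosomes."""
    chroms = [f"chr{i + 1}" for i in range(params.n_chrom)]
    per_chrom = [params.n_genes // params.n_chrom] * params.n_chrom
    for i in range(params.n_genes % params.n_chrom):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    for chrom, count in zip(chroms, per_chrom):
        lengths = rng.integers(params.gene_len_min, params.gene_len_max + 1, size=count)
        required = int(lengths.sum()) + params.min_gene_gap * (count + 1)
        if required > params.chrom_len:
            raise ParameterError(
                f"{count} genes need {required} bp but {chrom} has {params.chrom_len}"
            )
        slack = params.chrom_len - required
        extra = rng.multinomial(slack, np.full(count + 1, 1.0 / (count + 1)))
        cursor = 0
        for j in range(count):
            cursor += params.min_gene_gap + int(extra[j])
            start, end = cursor, cursor + int(lengths[j])
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start + 1 if strand == "+" else end
            n_ex = int(rng.integers(params.exons_min, params.exons_max + 1))
            cuts = np.sort(rng.choice(np.arange(1, end - start), size=2 * n_ex - 1,
                                      replace=False))
            bounds = np.concatenate([[0], cuts, [end - start]])
            exons = [
                GenomicInterval(chrom, start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                for k in range(n_ex)
            ]
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:04d}", symbol=f"SYM{gi}", chrom=chrom,
                    strand=strand, tss=tss, body=GenomicInterval(chrom, start, end),
                    exons=exons,
                )
            )
    return genes


def _make_loci(
    rng: np.random.Generator, params: SimParams
) -> tuple[list[Variant], list[Variant]]:
    """Leads plus proxy rows; proxies with r2 >= r2_min are the candidates."""
    traits = ("SBP", "DBP", "PP", "HTN")
    chroms = [f"chr{i + 1}" for i in range(params.n_chrom)]
    leads: list[Variant] = []
    proxies: list[Variant] = []
    used: set[tuple[str, int]] = set()
    for i in range(params.n_loci):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(params.proxy_span + 1,
                               params.chrom_len - params.proxy_span))
        while (chrom, pos) in used:
            pos = int(rng.integers(params.proxy_span + 1,
                                   params.chrom_len - params.proxy_span))
        used.add((chrom, pos))
        lead_id = f"rs{1000 + i}"
        leads.append(
            Variant(lead_id, chrom, pos, trait=traits[int(rng.integers(len(traits)))])
        )
        n_prox = int(rng.poisson(params.proxies_mean))
        for j in range(n_prox):
            off = 0
            while off == 0 or (chrom, pos + off) in used:
                off = int(rng.integers(-params.proxy_span, params.proxy_span + 1))
            used.add((chrom, pos + off))
            proxies.append(
                Variant(
                    f"{lead_id}_p{j + 1}", chrom, pos + off, role="proxy",
                    lead_id=lead_id,
                    ld_r2=round(float(rng.uniform(0.4, 1.0)), 4),
                )
            )
    return leads, proxies


def _plant_peaks(
    rng: np.random.Generator,
    params: SimParams,
    loci: Sequence[Locus],
    index: dict[str, Variant],
) -> tuple[dict[str, list[tuple[GenomicInterval, float]]], dict[str, int]]:
    tissues = [f"T{i + 1:02d}" for i in range(params.n_tissues)]
    enriched = sorted(
        rng.choice(tissues, size=params.n_enriched, replace=False).tolist()
    )
    peaks: dict[str, list[tuple[GenomicInterval, float]]] = {t: [] for t in tissues}
    planted_hits: dict[str, int] = {}
    n_hit = int(round(params.enriched_hit_frac * len(loci)))
    for tissue in enriched:
        chosen = rng.choice(len(loci), size=n_hit, replace=False)
        for li in sorted(chosen.tolist()):
            locus = loci[li]
            cid = sorted(locus.candidate_ids)[int(rng.integers(len(locus.candidate_ids)))]
            v = index[cid]
            start = max(0, v.pos - 1 - params.peak_width // 2)
            peaks[tissue].append(
                (GenomicInterval(v.chrom, start, start + params.peak_width),
                 round(float(rng.uniform(5, 20)), 3))
            )
        planted_hits[tissue] = n_hit
    chroms = [f"chr{i + 1}" for i in range(params.n_chrom)]
    for tissue in tissues:
        for _ in range(params.background_peaks):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, params.chrom_len - params.peak_width))
            peaks[tissue].append(
                (GenomicInterval(chrom, start, start + params.peak_width),
                 round(float(rng.uniform(1, 10)), 3))
            )
    return peaks, planted_hits


def _plant_interactions(
    rng: np.random.Generator,
    params: SimParams,
    genes: Sequence[GeneModel],
    index: dict[str, Variant],
) -> tuple[dict[str, list[InteractionPair]], list[tuple[str, str, str]], list[str]]:
    """Interaction pairs whose anchors contain exactly one planted SNP and
    overlap exactly one promoter, so link recovery is exact when background
    is zero."""
    tissues = [f"T{i + 1:02d}" for i in range(params.n_tissues)]
    windows = {g.gene_id: promoter_interval(g, params.promoter_up, params.promoter_down)
               for g in genes}
    win_by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in windows.values():
        win_by_chrom.setdefault(w.chrom, []).append(w)

    # candidates far enough from every promoter window that a +/-1 kb anchor
    # around them cannot touch one
    margin = params.promoter_margin
    eligible: dict[str, list[str]] = {}
    pos_by_chrom: dict[str, list[int]] = {}
    for cid in sorted(index):
        v = index[cid]
        pos_by_chrom.setdefault(v.chrom, []).append(v.pos - 1)
        p0 = v.pos - 1
        ok = all(
            p0 < w.start - margin or p0 >= w.end + margin
            for w in win_by_chrom.get(v.chrom, ())
        )
        if ok:
            eligible.setdefault(v.chrom, []).append(cid)
    for c in pos_by_chrom.values():
        c.sort()

    targets_pool = [g for g in genes if eligible.get(g.chrom)]
    if len(targets_pool) < params.n_hic_genes:
        raise ParameterError(
            f"only {len(targets_pool)} genes have an eligible same-chromosome SNP; "
            f"cannot plant {params.n_hic_genes} interaction targets"
        )
    targets = sorted(
        rng.choice([g.gene_id for g in targets_pool], size=params.n_hic_genes,
                   replace=False).tolist()
    )
    gene_of = {g.gene_id: g for g in genes}
    pairs: dict[str, list[InteractionPair]] = {t: [] for t in tissues}
    links: list[tuple[str, str, str]] = []
    for gid in targets:
        g = gene_of[gid]
        cid = eligible[g.chrom][int(rng.integers(len(eligible[g.chrom])))]
        v = index[cid]
        p0 = v.pos - 1
        allpos = pos_by_chrom[g.chrom]
        i = allpos.index(p0)
        la = 1000 if i == 0 else min(1000, p0 - allpos[i - 1] - 1)
        ra = 1000 if i == len(allpos) - 1 else min(1000, allpos[i + 1] - p0 - 1)
        anchor_snp = GenomicInterval(g.chrom, max(0, p0 - la), p0 + 1 + ra)
        anchor_prom = windows[gid]
        tissue = tissues[int(rng.integers(len(tissues)))]
        a, b = (anchor_snp, anchor_prom) if rng.random() < 0.5 else (anchor_prom, anchor_snp)
        pairs[tissue].append(
            InteractionPair(tissue, a, b, round(float(rng.uniform(1, 10)), 3))
        )
        links.append((cid, gid, tissue))
    chroms = [f"chr{i + 1}" for i in range(params.n_chrom)]
    for tissue in tissues:
        for _ in range(params.background_interactions):
            chrom = chroms[int(rng.integers(len(chroms)))]
            w = params.background_anchor_width
            s1 = int(rng.integers(0, params.chrom_len - w))
            s2 = int(rng.integers(0, params.chrom_len - w))
            pairs[tissue].append(
                InteractionPair(
                    tissue,
                    GenomicInterval(chrom, s1, s1 + w),
                    GenomicInterval(chrom, s2, s2 + w),
                    round(float(rng.uniform(1, 10)), 3),
                )
            )
    return pairs, links, targets


def simulate_bundle(
    params: SimParams = SimParams(),
    seed: int = 1,
    outdir: Optional[str] = None,
) -> tuple[Optional[dict[str, str]], SyntheticTruth, dict]:
    """Generate the full synthetic bundle.

    Returns ``(manifest, truth, data)``: the file manifest (None when no
    ``outdir`` is given), the ground truth, and the in-memory records
    (keys: leads, proxies, genes, loci, index, tracks, interactions, eqtls,
    cadd, druggable, drug_gene, config).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    tissues = [f"T{i + 1:02d}" for i in range(params.n_tissues)]
    if params.n_enriched > params.n_tissues:
        raise ParameterError("n_enriched exceeds n_tissues")

    genes = _place_genes(rng, params)
    leads, proxies = _make_loci(rng, params)
    loci, index = build_candidates(
        leads, proxies, mode="ld_then_window", r2_min=params.r2_min
    )
    peaks, planted_hits = _plant_peaks(rng, params, loci, index)
    interactions, hic_links, hic_genes = _plant_interactions(rng, params, genes, index)

    # eQTLs: echo a fraction of interaction links, then add eQTL-only genes
    n_conf = int(round(params.confirmed_frac * len(hic_genes)))
    confirmed = sorted(rng.choice(hic_genes, size=n_conf, replace=False).tolist())
    link_of = {gid: (vid, tid) for vid, gid, tid in hic_links}
    eqtls: list[EqtlRecord] = []
    eqtl_links: list[tuple[str, str, str]] = []
    for gid in confirmed:
        vid, _ = link_of[gid]
        tissue = tissues[int(rng.integers(len(tissues)))]
        eqtls.append(EqtlRecord(vid, gid, tissue, round(float(rng.normal()), 4),
                                qvalue=params.eqtl_q_planted))
        eqtl_links.append((vid, gid, tissue))
    non_targets = sorted(set(g.gene_id for g in genes) - set(hic_genes))
    added = sorted(rng.choice(non_targets, size=params.n_eqtl_only_genes,
                              replace=False).tolist())
    cand_ids = sorted(index)
    for gid in added:
        vid = cand_ids[int(rng.integers(len(cand_ids)))]
        tissue = tissues[int(rng.integers(len(tissues)))]
        eqtls.append(EqtlRecord(vid, gid, tissue, round(float(rng.normal()), 4),
                                qvalue=params.eqtl_q_planted))
        eqtl_links.append((vid, gid, tissue))
    for i in range(params.background_eqtls):
        gid = genes[int(rng.integers(len(genes)))].gene_id
        eqtls.append(
            EqtlRecord(f"bgSNP{i + 1}", gid, tissues[int(rng.integers(len(tissues)))],
                       round(float(rng.normal()), 4),
                       qvalue=round(float(rng.uniform(0.2, 1.0)), 4))
        )

    # CADD scores for leads: a fixed-size subset exceeds the threshold
    n_del = int(round(params.frac_deleterious * len(leads)))
    del_set = set(rng.choice([l.variant_id for l in leads], size=n_del,
                             replace=False).tolist())
    cadd: list[tuple[str, float]] = []
    for l in leads:
        if l.variant_id in del_set:
            score = round(12.38 + abs(float(rng.normal(0, 5))), 3)
        else:
            score = round(float(rng.uniform(0.1, 12.0)), 3)
        cadd.append((l.variant_id, score))

    # druggability over all genes; truth counts intersect the mapped set
    druggable: list[DruggabilityRecord] = []
    for g in genes:
        u = rng.random()
        acc = 0.0
        tier = "NONE"
        for name, frac in params.druggable_fracs:
            acc += frac
            if u < acc:
                tier = name
                break
        if tier != "NONE":
            druggable.append(DruggabilityRecord(g.gene_id, tier))
    mapped = sorted(set(hic_genes) | set(added))
    druggable_ids = {d.gene_id for d in druggable}
    mapped_druggable = [g for g in mapped if g in druggable_ids]
    n_anti = max(1, int(round(params.antihypertensive_frac * len(mapped_druggable)))) \
        if mapped_druggable else 0
    anti_genes = sorted(rng.choice(mapped_druggable, size=n_anti,
                                   replace=False).tolist()) if n_anti else []
    drug_gene: list[DrugGeneRecord] = []
    for k, gid in enumerate(anti_genes):
        atc = ANTIHYPERTENSIVE_ATC[int(rng.integers(len(ANTIHYPERTENSIVE_ATC)))]
        drug_gene.append(DrugGeneRecord(gid, f"antihyp_drug{k + 1}", atc))
    for k, d in enumerate(druggable):
        if d.gene_id not in anti_genes and rng.random() < 0.3:
            atc = OTHER_ATC[int(rng.integers(len(OTHER_ATC)))]
            drug_gene.append(DrugGeneRecord(d.gene_id, f"other_drug{k + 1}", atc))

    # inside/outside loci, computed on the same regions the pipeline builds
    gene_of = {g.gene_id: g for g in genes}
    n_inside = 0
    for gid in mapped:
        body = gene_of[gid].body
        if any(body.overlaps(locus.region) for locus in loci):
            n_inside += 1
    expected = {
        "n_candidates": len(index),
        "n_hic_genes": len(hic_genes),
        "n_confirmed": len(confirmed),
        "n_added": len(added),
        "n_total": len(hic_genes) + len(added),
        "n_druggable": len(mapped_druggable),
        "n_antihypertensive": len(anti_genes),
        "n_inside_loci": n_inside,
        "n_outside_loci": len(mapped) - n_inside,
        "n_unknown_position": 0,
    }
    truth = SyntheticTruth(
        seed=seed,
        params=asdict(params),
        candidate_ids=sorted(index),
        enriched_tissues=planted_hits,
        planted_interaction_links=sorted(hic_links),
        planted_eqtl_links=sorted(eqtl_links),
        confirmed_genes=confirmed,
        expected_counts=expected,
        n_deleterious_leads=n_del,
    )
    _check_truth_consistency(truth)

    config = PipelineConfig(
        r2_min=params.r2_min,
        promoter_up=params.promoter_up,
        promoter_down=params.promoter_down,
        seed=seed,
    )
    data = {
        "leads": leads, "proxies": proxies, "genes": genes, "loci": loci,
        "index": index,
        "tracks": {t: PeakTrack(t, "H3K4me3", peaks[t]) for t in tissues},
        "interactions": interactions, "eqtls": eqtls, "cadd": cadd,
        "druggable": druggable, "drug_gene": drug_gene, "config": config,
    }
    manifest = None
    if outdir is not None:
        manifest = _write_bundle(outdir, data, truth)
    return manifest, truth, data


def _check_truth_consistency(truth: SyntheticTruth) -> None:
    """Generator self-check: expected_counts must follow from planted links."""
    hic_genes = {g for _, g, _ in truth.planted_interaction_links}
    eqtl_genes = {g for _, g, _ in truth.planted_eqtl_links}
    both = hic_genes & eqtl_genes
    ec = truth.expected_counts
    derived = {
        "n_hic_genes": len(hic_genes),
        "n_confirmed": len(both),
        "n_added": len(eqtl_genes - hic_genes),
        "n_total": len(hic_genes | eqtl_genes),
    }
    for key, val in derived.items():
        if ec[key] != val:
            raise AssertionError(
                f"truth inconsistency: {key} stored {ec[key]} != derived {val}"
            )
    if sorted(both) != sorted(truth.confirmed_genes):
        raise AssertionError("truth inconsistency: confirmed gene set")


def _write_bundle(outdir, data: dict, truth: SyntheticTruth) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "tracks"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "interactions"), exist_ok=True)
    manifest: dict[str, str] = {}

    def put(name: str, rel: str) -> str:
        path = os.path.join(outdir, rel)
        manifest[name] = path
        return path

    gio.write_table(data["leads"], put("loci", "loci.tsv"), "loci")
    gio.write_table(data["proxies"], put("proxies", "proxies.tsv"), "proxies")
    gio.write_gene_table(data["genes"], put("genes", "genes.tsv"))
    gio.write_table(data["eqtls"], put("eqtl", "eqtl.tsv"), "eqtl")
    gio.write_table(data["cadd"], put("cadd", "cadd.tsv"), "cadd")
    gio.write_table(data["druggable"], put("druggable", "druggable.tsv"), "druggable")
    gio.write_table(data["drug_gene"], put("drug_gene", "drug_gene.tsv"), "drug_gene")
    for tissue in sorted(data["tracks"]):
        gio.write_bed(data["tracks"][tissue],
                      put(f"track:{tissue}", os.path.join("tracks", f"{tissue}.H3K4me3.bed")))
        gio.write_bedpe(data["interactions"][tissue],
                        put(f"bedpe:{tissue}", os.path.join("interactions", f"{tissue}.bedpe")))
    truth.to_json(put("truth", "truth.json"))
    data["config"].to_yaml(put("config", "config.yaml"))
    log.info("wrote synthetic bundle to %s (%d files)", outdir, len(manifest))
    return manifest


# ---------------------------------------------------------------------------
# index-variant catalog with prescribed marginals


def simulate_gwas_catalog(
    n_variants: int = 905,
    n_coding: int = 84,
    n_deleterious: int = 98,
    intronic_frac_of_noncoding: float = 0.45,
    seed: int = 1,
    outdir: Optional[str] = None,
    params: SimParams = SimParams(),
) -> tuple[list[Variant], list[GeneModel], list[tuple[str, float]], Optional[dict[str, str]]]:
    """An index-variant table with known marginal counts, plus its gene models.

    Emulates a published catalog of lead SNPs: exactly ``n_coding`` variants
    are placed inside exons (the default marginals 905/84 reproduce a 90.7%
    intronic+intergenic share), and exactly ``n_deleterious`` carry a CADD
    score strictly above the deleteriousness threshold.  Returns (variants,
    genes, cadd records, manifest).
    """
    if not (0 <= n_coding <= n_variants and 0 <= n_deleterious <= n_variants):
        raise ParameterError("marginal counts exceed n_variants")
    rng = np.random.default_rng(seed)
    genes = _place_genes(rng, params)
    traits = ("SBP", "DBP", "PP", "HTN")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    n_noncoding = n_variants - n_coding
    n_intronic = int(round(intronic_frac_of_noncoding * n_noncoding))
    labels = ["exonic"] * n_coding + ["intronic"] * n_intronic \
        + ["intergenic"] * (n_noncoding - n_intronic)
    rng.shuffle(labels)

    def in_exon(g: GeneModel, pos0: int) -> bool:
        return any(e.start <= pos0 < e.end for e in g.exons)

    used: set[tuple[str, int]] = set()
    variants: list[Variant] = []
    chroms = sorted(by_chrom)
    for i, label in enumerate(labels):
        while True:
            if label == "intergenic":
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos0 = int(rng.integers(0, params.chrom_len))
                if any(g.body.start <= pos0 < g.body.end for g in by_chrom[chrom]):
                    continue
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                g = by_chrom[chrom][int(rng.integers(len(by_chrom[chrom])))]
                pos0 = int(rng.integers(g.body.start, g.body.end))
                if (label == "exonic") != in_exon(g, pos0):
                    continue
            if (chrom, pos0) in used:
                continue
            used.add((chrom, pos0))
            variants.append(
                Variant(f"rs{10_000 + i}", chrom, pos0 + 1,
                        trait=traits[int(rng.integers(len(traits)))])
            )
            break

    del_ids = set(rng.choice([v.variant_id for v in variants], size=n_deleterious,
                             replace=False).tolist())
    cadd: list[tuple[str, float]] = []
    for v in variants:
        if v.variant_id in del_ids:
            score = round(12.38 + abs(float(rng.normal(0, 5))), 3)
        else:
            score = round(float(rng.uniform(0.1, 12.0)), 3)
        cadd.append((v.variant_id, score))

    manifest = None
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        manifest = {
            "loci": os.path.join(outdir, "catalog_loci.tsv"),
            "genes": os.path.join(outdir, "catalog_genes.tsv"),
            "cadd": os.path.join(outdir, "catalog_cadd.tsv"),
        }
        gio.write_table(variants, manifest["loci"], "loci")
        gio.write_gene_table(genes, manifest["genes"])
        gio.write_table(cadd, manifest["cadd"], "cadd")
    return variants, genes, cadd, manifest


# ---------------------------------------------------------------------------
# recovery harness


@dataclass
class RecoveryReport:
    """Planted-truth recovery of one bundle: per-stage precision/recall."""

    candidate_precision: float
    candidate_recall: float
    link_precision: float
    link_recall: float
    eqtl_precision: float
    eqtl_recall: float
    gene_precision: float
    gene_recall: float
    count_deltas: dict[str, int]

    @property
    def all_exact(self) -> bool:
        return (
            all(
                v == 1.0
                for v in (
                    self.candidate_precision, self.candidate_recall,
                    self.link_precision, self.link_recall,
                    self.eqtl_precision, self.eqtl_recall,
                    self.gene_precision, self.gene_recall,
                )
            )
            and all(d == 0 for d in self.count_deltas.values())
        )


def _pr(recovered: set, planted: set) -> tuple[float, float]:
    if not recovered and not planted:
        return 1.0, 1.0
    prec = len(recovered & planted) / len(recovered) if recovered else 0.0
    rec = len(recovered & planted) / len(planted) if planted else 1.0
    return prec, rec


def verify_truth_recovery(
    bundle_dir, truth: Optional[SyntheticTruth] = None
) -> RecoveryReport:
    """Run the full pipeline on a bundle and compare against its truth file.

    Noise-free bundles must come back with precision = recall = 1 at every
    stage and zero count deltas; bundles with background interactions may
    lose precision but never recall.
    """
    from .pipeline import run_bundle  # local import to avoid a cycle

    if truth is None:
        truth = SyntheticTruth.from_json(os.path.join(bundle_dir, "truth.json"))
    config = PipelineConfig.from_yaml(os.path.join(bundle_dir, "config.yaml"))
    if truth.params["promoter_up"] != config.promoter_up or \
            truth.params["promoter_down"] != config.promoter_down or \
            truth.params["r2_min"] != config.r2_min:
        raise ValueError("bundle config does not match the generator parameters")
    result = run_bundle(bundle_dir, config)

    cand_p, cand_r = _pr(set(result.candidates), set(truth.candidate_ids))
    rec_links = {(l.variant_id, l.gene_id, l.tissue_id) for l in result.links}
    link_p, link_r = _pr(rec_links, set(truth.planted_interaction_links))
    eq_p, eq_r = _pr(set(result.eqtl_links), set(truth.planted_eqtl_links))
    planted_genes = {g for _, g, _ in truth.planted_interaction_links} | {
        g for _, g, _ in truth.planted_eqtl_links
    }
    gene_p, gene_r = _pr({e.gene_id for e in result.evidence}, planted_genes)
    deltas = {
        k: result.summary.as_dict()[k] - v for k, v in truth.expected_counts.items()
    }
    return RecoveryReport(
        candidate_precision=cand_p, candidate_recall=cand_r,
        link_precision=link_p, link_recall=link_r,
        eqtl_precision=eq_p, eqtl_recall=eq_r,
        gene_precision=gene_p, gene_recall=gene_r,
        count_deltas=deltas,
    )
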