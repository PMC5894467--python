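"""Readers and writers for every external table and track the pipeline touches.

TSV tables carry a header row and are validated against named schemas; BED
peaks and BEDPE interaction pairs are whitespace-separated, 0-based and
half-open.  Every reader drops exact duplicate rows (with a logged count)
and reports validation failures with 1-based line numbers.  Writers sort
rows deterministically so re-running on identical inputs yields
byte-identical files.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence, Union

from .intervals import GenomicInterval
from .model import (
    DrugGeneRecord,
    DruggabilityRecord,
    EqtlRecord,
    GeneModel,
    InteractionPair,
    PeakTrack,
    Variant,
)

log = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RowError",
    "read_table",
    "write_table",
    "read_gene_table",
    "write_gene_table",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "write_outputs",
]


class SchemaError(ValueError):
    """The file's header does not match the named schema."""


class RowError(ValueError):
    """A data row failed to parse; the message carries the line number."""


# required columns per named schema (extra columns are ignored)
SCHEMAS: dict[str, tuple[str, ...]] = {
    "loci": ("variant_id", "chrom", "pos", "trait"),
    "proxies": ("lead_id", "proxy_id", "chrom", "pos", "r2"),
    "eqtl": ("variant_id", "gene_id", "tissue_id", "effect", "qvalue"),
    "cadd": ("variant_id", "cadd_phred"),
    "druggable": ("gene_id", "tier"),
    "drug_gene": ("gene_id", "drug_name", "atc_code"),
}

GENE_COLUMNS = (
    "gene_id",
    "symbol",
    "chrom",
    "strand",
    "tss",
    "start",
    "end",
    "exon_starts",
    "exon_ends",
)


def _read_rows(path: Union[str, os.PathLike], what: str) -> tuple[list[str], list[tuple[int, str]]]:
    """Read a TSV: returns (header fields, [(lineno, line), ...]) minus duplicates."""
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        log.warning("%s: %s is empty", what, path)
        return [], []
    header = lines[0].rstrip("\n").split("\t")
    seen: set[str] = set()
    rows: list[tuple[int, str]] = []
    n_dup = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line in seen:
            n_dup += 1
            continue
        seen.add(line)
        rows.append((lineno, line))
    if n_dup:
        log.info("%s: dropped %d duplicate rows from %s", what, n_dup, path)
    if not rows:
        log.warning("%s: %s has no data rows", what, path)
    return header, rows


def _column_map(header: list[str], required: Sequence[str], path) -> dict[str, int]:
    cols = {name: i for i, name in enumerate(header)}
    for name in required:
        if name not in cols:
            raise SchemaError(f"{path}: missing required column '{name}'")
    return cols


def _parse_float(text: str, lineno: int, path, col: str) -> Optional[float]:
    text = text.strip()
    if text in ("", "NA", "."):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise RowError(f"{path}:{lineno}: cannot parse {col} {text!r}") from exc


def _parse_int(text: str, lineno: int, path, col: str) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise RowError(f"{path}:{lineno}: cannot parse {col} {text!r}") from exc


def read_table(path, schema_name: str) -> list:
    """Read one of the named TSV schemas into typed records.

    Supported schemas: ``loci`` / ``proxies`` -> :class:`Variant`,
    ``eqtl`` -> :class:`EqtlRecord`, ``cadd`` -> ``(variant_id, score)``,
    ``druggable`` -> :class:`DruggabilityRecord`,
    ``drug_gene`` -> :class:`DrugGeneRecord`.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    header, rows = _read_rows(path, schema_name)
    if not header:
        return []
    cols = _column_map(header, SCHEMAS[schema_name], path)
    out: list = []
    for lineno, line in rows:
        f = line.split("\t")
        try:
            if schema_name == "loci":
                out.append(
                    Variant(
                        variant_id=f[cols["variant_id"]],
                        chrom=f[cols["chrom"]],
                        pos=_parse_int(f[cols["pos"]], lineno, path, "pos"),
                        trait=f[cols["trait"]],
                        role="lead",
                    )
                )
            elif schema_name == "proxies":
                out.append(
                    Variant(
                        variant_id=f[cols["proxy_id"]],
                        chrom=f[cols["chrom"]],
                        pos=_parse_int(f[cols["pos"]], lineno, path, "pos"),
                        role="proxy",
                        lead_id=f[cols["lead_id"]],
                        ld_r2=_parse_float(f[cols["r2"]], lineno, path, "r2"),
                    )
                )
            elif schema_name == "eqtl":
                out.append(
                    EqtlRecord(
                        variant_id=f[cols["variant_id"]],
                        gene_id=f[cols["gene_id"]],
                        tissue_id=f[cols["tissue_id"]],
                        effect=_parse_float(f[cols["effect"]], lineno, path, "effect") or 0.0,
                        qvalue=_parse_float(f[cols["qvalue"]], lineno, path, "qvalue"),
                    )
                )
            elif schema_name == "cadd":
                out.append(
                    (
                        f[cols["variant_id"]],
                        _parse_float(f[cols["cadd_phred"]], lineno, path, "cadd_phred"),
                    )
                )
            elif schema_name == "druggable":
                out.append(
                    DruggabilityRecord(gene_id=f[cols["gene_id"]], tier=f[cols["tier"]])
                )
            elif schema_name == "drug_gene":
                atc = f[cols["atc_code"]].strip()
                out.append(
                    DrugGeneRecord(
                        gene_id=f[cols["gene_id"]],
                        drug_name=f[cols["drug_name"]],
                        atc_code=atc or None,
                    )
                )
        except IndexError as exc:
            raise RowError(f"{path}:{lineno}: too few columns") from exc
        except ValueError as exc:
            if isinstance(exc, (RowError, SchemaError)):
                raise
            raise RowError(f"{path}:{lineno}: {exc}") from exc
    return out


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_table(records: Sequence, path, schema_name: str) -> None:
    """Write typed records back to a named-schema TSV (inverse of read_table)."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    header = SCHEMAS[schema_name]
    rows: list[tuple] = []
    for r in records:
        if schema_name == "loci":
            rows.append((r.variant_id, r.chrom, r.pos, r.trait))
        elif schema_name == "proxies":
            rows.append((r.lead_id, r.variant_id, r.chrom, r.pos, r.ld_r2))
        elif schema_name == "eqtl":
            rows.append((r.variant_id, r.gene_id, r.tissue_id, r.effect, r.qvalue))
        elif schema_name == "cadd":
            rows.append(tuple(r))
        elif schema_name == "druggable":
            rows.append((r.gene_id, r.tier))
        elif schema_name == "drug_gene":
            rows.append((r.gene_id, r.drug_name, r.atc_code))
    rows.sort(key=lambda t: tuple(_fmt(v) for v in t))
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_gene_table(path) -> list[GeneModel]:
    """Read the documented BED-like gene TSV into GeneModel records.

    Columns: gene_id, symbol, chrom, strand, tss (1-based), start, end
    (0-based half-open body) and comma-separated exon_starts / exon_ends.
    """
    header, rows = _read_rows(path, "genes")
    if not header:
        return []
    cols = _column_map(header, GENE_COLUMNS, path)
    genes: list[GeneModel] = []
    for lineno, line in rows:
        f = line.split("\t")
        try:
            chrom = f[cols["chrom"]]
            starts = [int(x) for x in f[cols["exon_starts"]].split(",") if x]
            ends = [int(x) for x in f[cols["exon_ends"]].split(",") if x]
            if len(starts) != len(ends):
                raise RowError(f"{path}:{lineno}: exon_starts/exon_ends length mismatch")
            genes.append(
                GeneModel(
                    gene_id=f[cols["gene_id"]],
                    symbol=f[cols["symbol"]],
                    chrom=chrom,
                    strand=f[cols["strand"]],
                    tss=_parse_int(f[cols["tss"]], lineno, path, "tss"),
                    body=GenomicInterval(
                        chrom,
                        _parse_int(f[cols["start"]], lineno, path, "start"),
                        _parse_int(f[cols["end"]], lineno, path, "end"),
                    ),
                    exons=[GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)],
                )
            )
        except IndexError as exc:
            raise RowError(f"{path}:{lineno}: too few columns") from exc
        except ValueError as exc:
            if isinstance(exc, (RowError, SchemaError)):
                raise
            raise RowError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.symbol,
                        g.chrom,
                        g.strand,
                        str(g.tss),
                        str(g.body.start),
                        str(g.body.end),
                        ",".join(str(e.start) for e in g.exons),
                        ",".join(str(e.end) for e in g.exons),
                    ]
                )
                + "\n"
            )


def read_bed(path, tissue_id: str, mark: str) -> PeakTrack:
    """Read a BED3/BED5 peak file into a merged, sorted PeakTrack.

    Coordinates are 0-based half-open; when a 5th column is present it is
    kept as the peak signal (maximum taken when peaks merge).
    """
    peaks: list[tuple[GenomicInterval, Optional[float]]] = []
    seen: set[str] = set()
    n_dup = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            if line in seen:
                n_dup += 1
                continue
            seen.add(line)
            f = line.split()
            if len(f) < 3:
                raise RowError(f"{path}:{lineno}: BED rows need >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise RowError(f"{path}:{lineno}: unparseable coordinates") from exc
            if start < 0:
                raise RowError(f"{path}:{lineno}: negative coordinate {start}")
            if start >= end:
                raise RowError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            signal = _parse_float(f[4], lineno, path, "signal") if len(f) >= 5 else None
            peaks.append((GenomicInterval(f[0], start, end), signal))
    if n_dup:
        log.info("bed: dropped %d duplicate rows from %s", n_dup, path)
    return PeakTrack(tissue_id, mark, peaks)


def write_bed(track: PeakTrack, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for i, (iv, sig) in enumerate(track.peaks):
            name = f"{track.tissue_id}_peak{i}"
            if sig is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt(sig)}\n")


def read_bedpe(path, tissue_id: str) -> list[InteractionPair]:
    """Read BEDPE interaction pairs (>= 6 columns, 0-based half-open anchors).

    Column 8, when present, is kept as the interaction score.  Pairs are
    returned in file order; trans pairs are flagged via ``is_trans`` and
    excluded by the mapping stage unless configured otherwise.
    """
    pairs: list[InteractionPair] = []
    seen: set[str] = set()
    n_dup = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line in seen:
                n_dup += 1
                continue
            seen.add(line)
            f = line.split()
            if len(f) < 6:
                raise SchemaError(f"{path}:{lineno}: BEDPE rows need >= 6 columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as exc:
                raise RowError(f"{path}:{lineno}: malformed anchor: {exc}") from exc
            score = _parse_float(f[7], lineno, path, "score") if len(f) >= 8 else None
            pairs.append(InteractionPair(tissue_id, a, b, score))
    if n_dup:
        log.info("bedpe: dropped %d duplicate rows from %s", n_dup, path)
    n_trans = sum(p.is_trans for p in pairs)
    if n_trans:
        log.info("bedpe: %s carries %d trans pairs", path, n_trans)
    return pairs


def write_bedpe(pairs: Sequence[InteractionPair], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for i, p in enumerate(pairs):
            fields = [
                p.anchor_a.chrom,
                str(p.anchor_a.start),
                str(p.anchor_a.end),
                p.anchor_b.chrom,
                str(p.anchor_b.start),
                str(p.anchor_b.end),
                f"pair{i}",
            ]
            if p.score is not None:
                fields.append(_fmt(p.score))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# result tables


def _write_tsv(path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_outputs(products: dict, outdir) -> dict[str, str]:
    """Write pipeline products to TSV files; returns {product: filename}.

    Recognised keys: ``variants`` (annotated Variant list), ``loci`` (Locus
    list), ``enrichment`` (TissueEnrichment list, ST3-shaped), ``links``
    (V2GLink list, ST5-shaped), ``evidence`` (GeneEvidence list) and
    ``summary`` (a Summary record).  Row order is deterministic, so identical
    inputs produce byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, records in products.items():
        fn = os.path.join(outdir, f"{name}.tsv")
        if name == "variants":
            rows = sorted(
                (
                    (v.variant_id, v.chrom, v.pos, v.trait, v.role, v.lead_id,
                     v.ld_r2, v.cadd_phred, v.context)
                    for v in records
                ),
                key=lambda r: r[0],
            )
            _write_tsv(fn, ("variant_id", "chrom", "pos", "trait", "role",
                            "lead_id", "ld_r2", "cadd_phred", "context"), rows)
        elif name == "loci":
            rows = sorted(
                (
                    (l.lead_id, l.region.chrom, l.region.start, l.region.end,
                     len(l.candidate_ids))
                    for l in records
                ),
                key=lambda r: r[0],
            )
            _write_tsv(fn, ("lead_id", "chrom", "start", "end", "n_candidates"), rows)
        elif name == "enrichment":
            rows = [
                (e.tissue_id, e.observed_hits, e.null_mean, e.null_sd,
                 e.fold, e.p_emp, e.q_bh, e.rank)
                for e in sorted(records, key=lambda e: e.rank)
            ]
            _write_tsv(fn, ("tissue_id", "observed_hits", "null_mean", "null_sd",
                            "fold", "p_emp", "q_bh", "rank"), rows)
        elif name == "links":
            rows = sorted(
                (l.gene_id, l.variant_id, l.tissue_id, l.source, l.interaction_index)
                for l in records
            )
            _write_tsv(fn, ("gene_id", "variant_id", "tissue_id", "source",
                            "interaction_index"), rows)
        elif name == "evidence":
            rows = []
            for ev in sorted(records, key=lambda e: e.gene_id):
                rows.append(
                    (
                        ev.gene_id,
                        ev.tier,
                        ",".join(sorted(ev.interaction_tissues)),
                        ",".join(sorted(ev.eqtl_tissues)),
                        ",".join(sorted(ev.supporting_variants)),
                        ev.inside_locus,
                        ev.druggability.tier if ev.druggability else "NONE",
                        ev.antihypertensive,
                        ";".join(
                            f"{d}:{a or 'NA'}"
                            for d, a in sorted(ev.druggability.drugs)
                        ) if ev.druggability else "",
                    )
                )
            _write_tsv(fn, ("gene_id", "tier", "interaction_tissues", "eqtl_tissues",
                            "supporting_variants", "inside_locus", "druggable_tier",
                            "antihypertensive", "drugs"), rows)
        elif name == "summary":
            fields = records.as_dict() if hasattr(records, "as_dict") else dict(records)
            _write_tsv(fn, tuple(fields), [tuple(fields.values())])
        else:
            raise ValueError(f"unknown product {name!r}")
        manifest[name] = fn
    return manifest
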