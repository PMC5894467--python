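import pytest

from gwas2gene import SimParams, simulate_bundle
from gwas2gene.intervals import GenomicInterval
from gwas2gene.model import GeneModel, Variant


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A default noise-free synthetic bundle, written once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest, truth, data = simulate_bundle(SimParams(), seed=7, outdir=str(outdir))
    return str(outdir), truth, data


def make_gene(gene_id, chrom, start, end, strand="+", tss=None, exons=()):
    """Compact GeneModel constructor for hand-built toy annotations."""
    if tss is None:
        tss = start + 1 if strand == "+" else end
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id.lower(),
        chrom=chrom,
        strand=strand,
        tss=tss,
        body=GenomicInterval(chrom, start, end),
        exons=[GenomicInterval(chrom, s, e) for s, e in exons],
    )


def make_variant(vid, chrom, pos, **kw):
    return Variant(vid, chrom, pos, **kw)
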