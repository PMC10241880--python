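import pytest

from techimera.model import (
    GeneModel,
    GenomicInterval,
    TELocation,
    TERecord,
    TranscriptModel,
)


def make_tx(tid, exons, strand="+", gene_id="g1", chrom="chr1"):
    return TranscriptModel(
        tid,
        gene_id,
        strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def make_gene(transcripts, gene_id="g1", biotype="protein_coding"):
    return GeneModel(gene_id, tuple(transcripts), biotype=biotype)


def make_te(te_id, start, end, chrom="chr1", superfamily="LTR/Copia",
            location=TELocation.INTRAGENIC_EXONIC, **kw):
    return TERecord(
        te_id,
        GenomicInterval(chrom, start, end, "."),
        family=te_id,
        superfamily=superfamily,
        location=location,
        **kw,
    )


@pytest.fixture
def two_isoform_ir_gene():
    """Textbook retained intron: A = [0,100)+[200,300); B = [0,300)."""
    a = make_tx("t.a", [(0, 100), (200, 300)])
    b = make_tx("t.b", [(0, 300)])
    return make_gene([a, b])


def mirror_interval(iv: GenomicInterval, length: int, flip_strand: bool):
    strand = iv.strand
    if flip_strand and strand in "+-":
        strand = "-" if strand == "+" else "+"
    return GenomicInterval(iv.chrom, length - iv.end, length - iv.start, strand)


def mirror_gene(gene: GeneModel, length: int, flip_strand: bool) -> GeneModel:
    txs = []
    for t in gene.transcripts:
        strand = t.strand
        if flip_strand:
            strand = "-" if strand == "+" else "+"
        exons = tuple(
            sorted(
                (mirror_interval(e, length, flip_strand) for e in t.exons),
                key=lambda iv: iv.start,
            )
        )
        txs.append(TranscriptModel(t.transcript_id, t.gene_id, strand, exons))
    return GeneModel(gene.gene_id, tuple(txs), biotype=gene.biotype)


def mirror_te(te: TERecord, length: int) -> TERecord:
    return TERecord(
        te.te_id,
        mirror_interval(te.interval, length, flip_strand=False),
        family=te.family,
        superfamily=te.superfamily,
        location=te.location,
        removed_gene_like=te.removed_gene_like,
        host_genes=te.host_genes,
    )
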