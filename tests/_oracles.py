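"""Independent per-base oracles and random-instance generators.

The oracle classifies TEs by explicit per-base bitmaps (numpy boolean
masks over the chromosome), never by interval arithmetic, so it checks the
interval-tree implementation from an independent direction.
"""

from __future__ import annotations

import numpy as np

from techimera.model import (
    ClassificationConfig,
    GeneModel,
    GenomicInterval,
    TERecord,
    TranscriptModel,
)


def _mask(length: int, intervals) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for iv in intervals:
        m[iv.start : iv.end] = True
    return m


def oracle_classify(genes, tes, cfg: ClassificationConfig, chrom_len: dict[str, int]):
    """Per-base reimplementation of gene-like removal + location classes.

    Returns dict te_id -> (removed_gene_like, location string, host gene ids)
    and the set of surviving gene ids.
    """
    exonic_masks = {
        g.gene_id: _mask(chrom_len[g.chrom], [e for t in g.transcripts for e in t.exons])
        for g in genes
    }
    span_masks = {g.gene_id: _mask(chrom_len[g.chrom], [g.span]) for g in genes}

    def te_cov(mask: np.ndarray, te: TERecord) -> int:
        return int(mask[te.interval.start : te.interval.end].sum())

    # gene-like removal
    removed_genes: set[str] = set()
    flagged_tes: set[str] = set()
    frac = cfg.gene_like_reciprocal_fraction
    for gene in genes:
        if gene.biotype == "transposable_element_gene":
            removed_genes.add(gene.gene_id)
            continue
        exonic = exonic_masks[gene.gene_id]
        exonic_len = int(exonic.sum())
        for te in tes:
            if te.chrom != gene.chrom or exonic_len == 0:
                continue
            cov_gene = te_cov(exonic, te)
            cov_te = te_cov(span_masks[gene.gene_id], te)
            if cov_gene >= frac * exonic_len and cov_te >= frac * te.interval.length:
                removed_genes.add(gene.gene_id)
                flagged_tes.add(te.te_id)

    surviving = [g for g in genes if g.gene_id not in removed_genes]

    result = {}
    for te in tes:
        if te.te_id in flagged_tes:
            result[te.te_id] = (True, "unclassified", ())
            continue
        hosts = []
        for gene in surviving:
            if gene.chrom != te.chrom:
                continue
            if te_cov(span_masks[gene.gene_id], te) >= cfg.min_intragenic_overlap_bp:
                hosts.append(gene.gene_id)
        if not hosts:
            result[te.te_id] = (False, "intergenic", ())
            continue
        exonic = any(te_cov(exonic_masks[gid], te) >= 1 for gid in hosts)
        loc = "intragenic_exonic" if exonic else "intragenic_intronic"
        result[te.te_id] = (False, loc, tuple(sorted(hosts)))
    return result, {g.gene_id for g in surviving}


def oracle_exonic_overlap(tx: TranscriptModel, te: TERecord, chrom_len: int) -> int:
    """Per-base total exonic overlap of one transcript with one TE."""
    if tx.chrom != te.chrom:
        return 0
    emask = _mask(chrom_len, tx.exons)
    return int(emask[te.interval.start : te.interval.end].sum())


# ---------------------------------------------------------------------------
# random instances


def random_instance(rng: np.random.Generator, max_genes: int = 50, max_tes: int = 200):
    """A random annotation instance on one chromosome.

    Genes have 1-3 isoforms of 1-4 exons; TEs are random intervals, a few of
    which are copied from gene exons so the gene-like rule fires sometimes.
    """
    n_genes = int(rng.integers(1, max_genes + 1))
    n_tes = int(rng.integers(1, max_tes + 1))
    stride = 1200
    chrom = "chrT"
    chrom_len = n_genes * stride + 400

    genes = []
    for gi in range(n_genes):
        offset = 100 + gi * stride
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"g{gi}"
        n_tx = int(rng.integers(1, 4))
        txs = []
        for ti in range(n_tx):
            n_ex = int(rng.integers(1, 5))
            # random sorted boundaries within an 800 bp window
            cuts = np.sort(rng.choice(np.arange(0, 800, 10), size=2 * n_ex, replace=False))
            exons = []
            for k in range(n_ex):
                s, e = int(cuts[2 * k]), int(cuts[2 * k + 1])
                if e - s < 10:
                    e = s + 10
                exons.append(GenomicInterval(chrom, offset + s, offset + e, strand))
            # enforce non-overlap after widening
            cleaned = [exons[0]]
            for iv in exons[1:]:
                if iv.start < cleaned[-1].end:
                    iv = GenomicInterval(
                        chrom, cleaned[-1].end + 5, cleaned[-1].end + 5 + iv.length, strand
                    )
                cleaned.append(iv)
            txs.append(
                TranscriptModel(f"{gene_id}.t{ti}", gene_id, strand, tuple(cleaned))
            )
        biotype = (
            "transposable_element_gene" if rng.random() < 0.05 else "protein_coding"
        )
        genes.append(GeneModel(gene_id, tuple(txs), biotype=biotype))

    tes = []
    for ti in range(n_tes):
        if rng.random() < 0.1:
            # copy a gene's exonic hull -> likely gene-like
            gene = genes[int(rng.integers(0, n_genes))]
            iv = gene.span
            te_iv = GenomicInterval(chrom, iv.start, iv.end, ".")
        else:
            start = int(rng.integers(0, chrom_len - 400))
            length = int(rng.integers(30, 400))
            te_iv = GenomicInterval(chrom, start, start + length, ".")
        tes.append(TERecord(f"te{ti}", te_iv))
    return genes, tes, {chrom: chrom_len}
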