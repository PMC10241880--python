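"""TE location classification.

Three successive filters mirror the front half of the chimeric-transcript
pipeline: (1) drop gene models that are TE annotations in disguise, (2) split
the remaining TEs into intergenic vs intragenic by gene-span overlap, and
(3) split intragenic TEs into exonic vs intronic against the union of all
host-gene isoforms.  Strand is ignored throughout: antisense TE insertions
form chimeric transcripts just as sense ones do.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

from intervaltree import IntervalTree

from .model import (
    ClassificationConfig,
    GeneModel,
    GenomicInterval,
    TELocation,
    TERecord,
    total_overlap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "remove_gene_like_tes",
    "classify_intergenic",
    "classify_exonic_intronic",
    "classify_tes",
]


def _interval_trees(items, key):
    """chrom -> IntervalTree of (start, end) -> item."""
    trees: dict[str, IntervalTree] = {}
    for item in items:
        iv = key(item)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, item)
    return trees


def remove_gene_like_tes(
    genes: Sequence[GeneModel],
    tes: Sequence[TERecord],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> tuple[list[GeneModel], list[TERecord]]:
    """Drop gene models that are really TE annotations.

    A gene is removed, with all its transcripts, when (a) its biotype is
    ``transposable_element_gene``, or (b) a TE covers at least
    ``cfg.gene_like_reciprocal_fraction`` of the gene's exonic length while
    the gene span reciprocally covers the same fraction of the TE.  TEs that
    trigger rule (b) are flagged ``removed_gene_like`` and are excluded from
    all downstream chimera calling.

    Returns (surviving genes, all TEs with flags set).  Pure filter: inputs
    are not mutated.
    """
    frac = cfg.gene_like_reciprocal_fraction
    te_trees = _interval_trees(tes, lambda te: te.interval)
    flagged_te_ids: set[str] = set()
    kept_genes: list[GeneModel] = []
    n_biotype = 0
    for gene in genes:
        if gene.biotype == "transposable_element_gene":
            n_biotype += 1
            continue
        exonic = gene.exonic_union
        exonic_len = sum(iv.length for iv in exonic)
        span = gene.span
        gene_like = False
        tree = te_trees.get(gene.chrom)
        if tree is not None and exonic_len > 0:
            for hit in tree.overlap(span.start, span.end):
                te: TERecord = hit.data
                te_cov_of_gene = total_overlap(exonic, te.interval)
                gene_cov_of_te = span.overlap_bp(te.interval)
                if (
                    te_cov_of_gene >= frac * exonic_len
                    and gene_cov_of_te >= frac * te.interval.length
                ):
                    gene_like = True
                    flagged_te_ids.add(te.te_id)
        if gene_like:
            continue
        kept_genes.append(gene)

    out_tes = [
        replace(
            te,
            removed_gene_like=te.te_id in flagged_te_ids,
            location=TELocation.UNCLASSIFIED,
            host_genes=(),
        )
        for te in tes
    ]
    n_removed = len(genes) - len(kept_genes)
    if n_removed:
        logger.info(
            "removed %d gene-like gene models (%d by biotype); flagged %d TEs",
            n_removed,
            n_biotype,
            len(flagged_te_ids),
        )
    return kept_genes, out_tes


def classify_intergenic(
    tes: Sequence[TERecord],
    genes: Sequence[GeneModel],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> list[TERecord]:
    """Assign intergenic vs intragenic by overlap with surviving gene spans.

    A TE is intragenic when its overlap with at least one gene span reaches
    ``cfg.min_intragenic_overlap_bp``; all qualifying genes are recorded as
    hosts (a TE straddling two genes gets both).  Gene-like TEs keep their
    ``unclassified`` location.
    """
    gene_trees = _interval_trees(genes, lambda g: g.span)
    out: list[TERecord] = []
    for te in tes:
        if te.removed_gene_like:
            out.append(replace(te, location=TELocation.UNCLASSIFIED, host_genes=()))
            continue
        hosts = []
        tree = gene_trees.get(te.chrom)
        if tree is not None:
            for hit in tree.overlap(te.interval.start, te.interval.end):
                gene: GeneModel = hit.data
                if gene.span.overlap_bp(te.interval) >= cfg.min_intragenic_overlap_bp:
                    hosts.append(gene.gene_id)
        if hosts:
            out.append(
                replace(
                    te,
                    location=TELocation.INTRAGENIC_INTRONIC,  # refined in step 3
                    host_genes=tuple(sorted(hosts)),
                )
            )
        else:
            out.append(replace(te, location=TELocation.INTERGENIC, host_genes=()))
    return out


def classify_exonic_intronic(
    tes: Sequence[TERecord],
    genes: Sequence[GeneModel],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> list[TERecord]:
    """Refine intragenic TEs into exonic vs intronic.

    A TE is exonic when it overlaps at least one base of any exon of any
    isoform of a host gene; a TE whose gene-span overlap is confined to
    intronic bases is intronic.  With ``cfg.exonic_priority`` (default) a TE
    overlapping both exonic and intronic bases counts as exonic — such TEs
    are the natural intron-retention candidates.
    """
    by_id = {g.gene_id: g for g in genes}
    out: list[TERecord] = []
    for te in tes:
        if te.location not in (
            TELocation.INTRAGENIC_INTRONIC,
            TELocation.INTRAGENIC_EXONIC,
        ):
            out.append(te)
            continue
        exonic = False
        for gid in te.host_genes:
            gene = by_id.get(gid)
            if gene is None:
                continue
            if total_overlap(gene.exonic_union, te.interval) >= 1:
                exonic = True
                break
        loc = TELocation.INTRAGENIC_EXONIC if exonic else TELocation.INTRAGENIC_INTRONIC
        out.append(replace(te, location=loc))
    return out


def classify_tes(
    genes: Sequence[GeneModel],
    tes: Sequence[TERecord],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> tuple[list[GeneModel], list[TERecord]]:
    """Run all three classification steps; returns (surviving genes, TEs)."""
    kept_genes, tes1 = remove_gene_like_tes(genes, tes, cfg)
    tes2 = classify_intergenic(tes1, kept_genes, cfg)
    tes3 = classify_exonic_intronic(tes2, kept_genes, cfg)
    return kept_genes, tes3


def location_counts(tes: Sequence[TERecord]) -> dict[str, int]:
    """Histogram of TE location classes (gene-like TEs counted separately)."""
    counts = {
        "removed_gene_like": 0,
        "intergenic": 0,
        "intragenic_intronic": 0,
        "intragenic_exonic": 0,
        "unclassified": 0,
    }
    for te in tes:
        if te.removed_gene_like:
            counts["removed_gene_like"] += 1
        else:
            counts[te.location.value] += 1
    return counts
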