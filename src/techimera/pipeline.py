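"""End-to-end orchestration of the chimeric-transcript analysis.

`run_pipeline` wires the stages together: TE classification, chimera
calling, event classification, superfamily enrichment, splice-site motif
extraction, poly(A) intersection and methylation summaries.  Optional
inputs (genome, poly(A) anchors, cytosine table) switch their stages on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import enrichment as enr
from . import methylation as meth
from . import polya as pa
from .annotations import GenomeSequence, ResultBundle
from .chimera import call_ate_g_isoforms, detect_te_g_transcripts, summarize_catalog
from .model import (
    ChimeraCall,
    ClassificationConfig,
    EventCall,
    EventConfig,
    GeneModel,
    GenomicInterval,
    TERecord,
)
from .te_classify import classify_tes, location_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    genes: list[GeneModel]
    tes: list[TERecord]
    chimeras: list[ChimeraCall]
    events: list[EventCall]
    summary: dict
    location_counts: dict
    tables: ResultBundle
    splice_windows: list = field(default_factory=list)
    polya_summary: dict = field(default_factory=dict)


def _chimera_table(chimeras: Sequence[ChimeraCall]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "gene_id": c.gene_id,
            "te_id": c.te_id,
            "overlap_bp": c.overlap_bp,
            "exon_positions": ",".join(sorted(c.exon_positions)),
            "te_location": c.te_location.value,
        }
        for c in chimeras
    ]
    return pd.DataFrame(rows)


def _event_table(
    events: Sequence[EventCall], tes: Sequence[TERecord]
) -> pd.DataFrame:
    sf = {te.te_id: te.superfamily for te in tes}
    rows = [
        {
            "gene_id": e.gene_id,
            "te_id": e.te_id,
            "te_superfamily": sf.get(e.te_id, "Unknown"),
            "event": e.event.value,
            "subtype": e.subtype.value,
            "iso_with": e.iso_with,
            "iso_without": e.iso_without,
            "chrom": e.region.chrom,
            "region_start": e.region.start,
            "region_end": e.region.end,
            "strand": e.region.strand,
            "overlap_bp": e.overlap_bp,
        }
        for e in events
    ]
    return pd.DataFrame(rows)


def run_pipeline(
    genes: Sequence[GeneModel],
    tes: Sequence[TERecord],
    genome: Optional[GenomeSequence] = None,
    polya_anchors: Optional[Sequence[GenomicInterval]] = None,
    cytosines: Optional[pd.DataFrame] = None,
    class_cfg: ClassificationConfig = ClassificationConfig(),
    event_cfg: EventConfig = EventConfig(),
    polya_flank: int = 10,
    meth_q_threshold: float = 0.01,
    control_contig: str = "control_mito",
    uniform_background: bool = False,
) -> PipelineResult:
    """Run all stages on in-memory annotations."""
    kept_genes, classified = classify_tes(list(genes), list(tes), class_cfg)
    chimeras = detect_te_g_transcripts(kept_genes, classified, event_cfg)
    events = call_ate_g_isoforms(chimeras, kept_genes, classified, event_cfg)
    summary = summarize_catalog(chimeras, events, classified, kept_genes)

    tables = ResultBundle(
        chimeras=_chimera_table(chimeras),
        events=_event_table(events, classified),
        enrichment=enr.enrichment_table(classified, events),
    )

    windows: list = []
    if genome is not None and events:
        windows = enr.extract_ir_splice_sites(events, kept_genes, classified, genome)
        if windows:
            background = (
                {b: 0.25 for b in "ACGT"}
                if uniform_background
                else genome.base_frequencies()
            )
            tables.motifs = enr.position_nucleotide_enrichment(
                windows, background=background
            )

    polya_summary: dict = {}
    if polya_anchors is not None:
        sites = pa.build_polya_windows(polya_anchors, flank=polya_flank)
        atts = pa.atts_tes(events, classified)
        table, polya_summary = pa.tes_with_polya(atts, sites)
        tables.polya_overlap = table

    if cytosines is not None:
        rates = meth.estimate_error_rate(cytosines, control_contig)
        called = meth.call_sites(cytosines, rates, q_threshold=meth_q_threshold)
        summaries = meth.te_methylation(called, classified)
        tables.methylation = meth.methylation_table(summaries)

    return PipelineResult(
        genes=kept_genes,
        tes=classified,
        chimeras=chimeras,
        events=events,
        summary=summary,
        location_counts=location_counts(classified),
        tables=tables,
        splice_windows=windows,
        polya_summary=polya_summary,
    )
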