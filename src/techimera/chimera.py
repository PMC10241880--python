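"""Chimeric TE-gene transcript calling and alternative-isoform events.

A TE-G transcript is a transcript whose exons overlap a transposable
element.  When a gene expresses several isoforms, the isoform differences
around a TE are classified into local RNA-processing events by pairwise
comparison of exon chains:

* IR   — an intron of one isoform retained inside a single exon of the other
* ES   — an internal exon present in one isoform, absent from the other
* A5SS — two introns share their acceptor but differ in donor
* A3SS — two introns share their donor but differ in acceptor
* ATSS — distinct transcription start sites (subtype AFE when the first
         exons do not overlap at all)
* ATTS — distinct termination sites (subtype ALE for disjoint last exons)

All rules are strand-aware: donor means the 5' splice site of an intron on
the transcript strand, and the TSS/TTS are strand-polar points.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    ChimeraCall,
    EventCall,
    EventConfig,
    EventSubtype,
    EventType,
    GeneModel,
    GenomicInterval,
    TERecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseEvent",
    "detect_te_g_transcripts",
    "enumerate_pairwise_events",
    "call_ate_g_isoforms",
    "summarize_catalog",
]


@dataclass(frozen=True)
class PairwiseEvent:
    """A TE-agnostic event between two isoforms of one gene.

    ``region`` is the hull of the differential segment; ``segments`` are the
    exonic sub-intervals of the region in the isoform that carries the extra
    sequence (used for TE-overlap tests — for IR and ES the region is a
    single contiguous segment).
    """

    event: EventType
    subtype: EventSubtype
    region: GenomicInterval
    segments: tuple[GenomicInterval, ...]
    iso_with: str
    iso_without: str


# ---------------------------------------------------------------------------
# step 4: TE-G transcript detection


def detect_te_g_transcripts(
    genes: Sequence[GeneModel],
    tes: Sequence[TERecord],
    cfg: EventConfig = EventConfig(),
) -> list[ChimeraCall]:
    """Call (transcript, TE) chimeras by total exonic overlap.

    One call per pair with summed exon overlap >= ``cfg.min_chimera_overlap_bp``.
    Gene-like (removed) TEs never produce calls.  Exon positions are
    classified first/internal/last on the transcript's own chain, by strand;
    a single-exon transcript's exon is both first and last.
    """
    te_trees: dict[str, IntervalTree] = {}
    for te in tes:
        if te.removed_gene_like:
            continue
        iv = te.interval
        te_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, te)

    calls: list[ChimeraCall] = []
    for gene in genes:
        tree = te_trees.get(gene.chrom)
        if tree is None:
            continue
        for tx in gene.transcripts:
            span = tx.span
            candidates = {hit.data.te_id: hit.data for hit in tree.overlap(span.start, span.end)}
            for te_id in sorted(candidates):
                te = candidates[te_id]
                overlap = 0
                positions: set[str] = set()
                n = len(tx.exons)
                for i, exon in enumerate(tx.exons):
                    bp = exon.overlap_bp(te.interval)
                    if bp <= 0:
                        continue
                    overlap += bp
                    # first/last by transcript strand
                    is_first = (i == 0) if tx.strand == "+" else (i == n - 1)
                    is_last = (i == n - 1) if tx.strand == "+" else (i == 0)
                    if is_first:
                        positions.add("first")
                    if is_last:
                        positions.add("last")
                    if not is_first and not is_last:
                        positions.add("internal")
                if overlap >= cfg.min_chimera_overlap_bp:
                    calls.append(
                        ChimeraCall(
                            transcript_id=tx.transcript_id,
                            gene_id=gene.gene_id,
                            te_id=te.te_id,
                            overlap_bp=overlap,
                            exon_positions=frozenset(positions),
                            te_location=te.location,
                        )
                    )
    return calls


# ---------------------------------------------------------------------------
# step 5: pairwise event enumeration


def _donor_acceptor(intron: GenomicInterval, strand: str) -> tuple[int, int]:
    """Junction point coordinates (donor, acceptor) of an intron."""
    if strand == "+":
        return intron.start, intron.end
    return intron.end, intron.start


def _covering_exon(
    tx: TranscriptModel, region: GenomicInterval
) -> Optional[GenomicInterval]:
    for e in tx.exons:
        if e.start <= region.start and e.end >= region.end:
            return e
    return None


def _pair_events(
    a: TranscriptModel, b: TranscriptModel, cfg: EventConfig
) -> list[PairwiseEvent]:
    tol = cfg.boundary_tolerance_bp
    chrom = a.chrom
    strand = a.strand
    events: list[PairwiseEvent] = []

    # --- IR: intron of X retained inside a single exon of Y ---------------
    for x, y in ((a, b), (b, a)):
        for j, intron in enumerate(x.introns):
            for e in y.exons:
                if not (e.start <= intron.start and intron.end <= e.end):
                    continue
                left, right = x.exons[j], x.exons[j + 1]
                if abs(left.start - e.start) <= tol and abs(right.end - e.end) <= tol:
                    region = GenomicInterval(chrom, intron.start, intron.end, strand)
                    events.append(
                        PairwiseEvent(
                            EventType.IR,
                            EventSubtype.NONE,
                            region,
                            (region,),
                            iso_with=y.transcript_id,  # Y retains the intron
                            iso_without=x.transcript_id,
                        )
                    )

    # --- ES: internal exon of X absent from Y -----------------------------
    for x, y in ((a, b), (b, a)):
        for j in range(1, len(x.exons) - 1):
            exon = x.exons[j]
            if any(exon.overlap_bp(e) > 0 for e in y.exons):
                continue
            up, down = x.exons[j - 1], x.exons[j + 1]
            shares_up = any(abs(up.end - e.end) <= tol for e in y.exons)
            shares_down = any(abs(down.start - e.start) <= tol for e in y.exons)
            if shares_up and shares_down:
                region = GenomicInterval(chrom, exon.start, exon.end, strand)
                events.append(
                    PairwiseEvent(
                        EventType.ES,
                        EventSubtype.NONE,
                        region,
                        (region,),
                        iso_with=x.transcript_id,  # X includes the exon
                        iso_without=y.transcript_id,
                    )
                )

    # --- A5SS / A3SS: intron pairs sharing one junction --------------------
    for ia in a.introns:
        for ib in b.introns:
            da, aa = _donor_acceptor(ia, strand)
            db, ab = _donor_acceptor(ib, strand)
            for ev_type, pa, pb, qa, qb in (
                (EventType.A5SS, aa, ab, da, db),  # shared acceptor, alt donors
                (EventType.A3SS, da, db, aa, ab),  # shared donor, alt acceptors
            ):
                if abs(pa - pb) > tol or abs(qa - qb) <= tol:
                    continue
                lo, hi = min(qa, qb), max(qa, qb)
                region = GenomicInterval(chrom, lo, hi, strand)
                # the extending isoform's exon must cover the whole region;
                # this rejects first/last-exon and skipped-exon artefacts
                cov_a = _covering_exon(a, region)
                cov_b = _covering_exon(b, region)
                if (cov_a is None) == (cov_b is None):
                    continue
                extender = a if cov_a is not None else b
                other = b if cov_a is not None else a
                events.append(
                    PairwiseEvent(
                        ev_type,
                        EventSubtype.NONE,
                        region,
                        (region,),
                        iso_with=extender.transcript_id,
                        iso_without=other.transcript_id,
                    )
                )

    # --- ATSS / ATTS: alternative terminal segments ------------------------
    for ev_type, point, terminal_exon, min_shift, subtype in (
        (
            EventType.ATSS,
            lambda t: t.tss,
            lambda t: t.first_exon,
            cfg.atss_min_shift_bp,
            EventSubtype.AFE,
        ),
        (
            EventType.ATTS,
            lambda t: t.tts,
            lambda t: t.last_exon,
            cfg.atts_min_shift_bp,
            EventSubtype.ALE,
        ),
    ):
        pa, pb = point(a), point(b)
        ea, eb = terminal_exon(a), terminal_exon(b)
        disjoint = ea.overlap_bp(eb) == 0
        if abs(pa - pb) < min_shift and not disjoint:
            continue
        if pa == pb:
            continue
        # the extending isoform has the more 5'-extreme TSS (resp. more
        # 3'-extreme TTS); both cases reduce to "terminus farther from the
        # gene body", which for either event type on either strand is simply
        # the isoform whose terminal point lies outside the other's.
        if ev_type is EventType.ATSS:
            extreme_is_a = (pa < pb) if strand == "+" else (pa > pb)
        else:
            extreme_is_a = (pa > pb) if strand == "+" else (pa < pb)
        ext, other = (a, b) if extreme_is_a else (b, a)
        lo, hi = min(pa, pb), max(pa, pb)
        segments = tuple(
            GenomicInterval(
                chrom, max(e.start, lo), min(e.end, hi), strand
            )
            for e in ext.exons
            if max(e.start, lo) < min(e.end, hi)
        )
        if not segments:
            continue
        region = GenomicInterval(
            chrom, segments[0].start, segments[-1].end, strand
        )
        events.append(
            PairwiseEvent(
                ev_type,
                subtype if disjoint else EventSubtype.NONE,
                region,
                segments,
                iso_with=ext.transcript_id,
                iso_without=other.transcript_id,
            )
        )

    # dedupe identical findings reached via different intron pairs
    seen = set()
    unique = []
    for ev in events:
        key = (ev.event, ev.subtype, ev.region, ev.iso_with, ev.iso_without)
        if key not in seen:
            seen.add(key)
            unique.append(ev)
    return unique


def enumerate_pairwise_events(
    gene: GeneModel, cfg: EventConfig = EventConfig()
) -> list[PairwiseEvent]:
    """All pairwise events among a gene's isoforms.

    Unstranded transcripts are skipped with a warning; pairs on opposite
    strands (possible in merged annotations) are likewise skipped.
    """
    events: list[PairwiseEvent] = []
    txs = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    for a, b in itertools.combinations(txs, 2):
        if a.strand not in ("+", "-") or b.strand not in ("+", "-"):
            logger.warning(
                "gene %s: skipping unstranded isoform pair (%s, %s)",
                gene.gene_id,
                a.transcript_id,
                b.transcript_id,
            )
            continue
        if a.strand != b.strand:
            logger.warning(
                "gene %s: skipping opposite-strand isoform pair (%s, %s)",
                gene.gene_id,
                a.transcript_id,
                b.transcript_id,
            )
            continue
        events.extend(_pair_events(a, b, cfg))
    return events


# ---------------------------------------------------------------------------
# TE association


def call_ate_g_isoforms(
    chimeras: Sequence[ChimeraCall],
    genes: Sequence[GeneModel],
    tes: Sequence[TERecord],
    cfg: EventConfig = EventConfig(),
) -> list[EventCall]:
    """Associate pairwise isoform events with the TEs that drive them.

    For every gene with >= 2 isoforms, each pairwise event yields one
    EventCall per chimeric TE of that gene whose interval overlaps the
    event's exonic segments by >= 1 bp.  Identical (event, subtype, region,
    TE) findings reached through different isoform pairs are reported once
    (first pair in transcript-id order kept).
    """
    chimeric_by_gene: dict[str, set[str]] = {}
    for call in chimeras:
        chimeric_by_gene.setdefault(call.gene_id, set()).add(call.te_id)
    te_by_id = {te.te_id: te for te in tes}

    calls: list[EventCall] = []
    for gene in genes:
        if len(gene.transcripts) < 2:
            continue
        te_ids = chimeric_by_gene.get(gene.gene_id)
        if not te_ids:
            continue
        candidates = [
            te_by_id[t] for t in sorted(te_ids) if not te_by_id[t].removed_gene_like
        ]
        seen: set[tuple] = set()
        for ev in enumerate_pairwise_events(gene, cfg):
            for te in candidates:
                bp = sum(seg.overlap_bp(te.interval) for seg in ev.segments)
                if bp < 1:
                    continue
                key = (ev.event, ev.subtype, ev.region, te.te_id)
                if key in seen:
                    continue
                seen.add(key)
                calls.append(
                    EventCall(
                        gene_id=gene.gene_id,
                        te_id=te.te_id,
                        event=ev.event,
                        subtype=ev.subtype,
                        iso_with=ev.iso_with,
                        iso_without=ev.iso_without,
                        region=ev.region,
                        overlap_bp=bp,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# catalogue summary


def summarize_catalog(
    chimeras: Sequence[ChimeraCall],
    events: Sequence[EventCall],
    tes: Sequence[TERecord],
    genes: Sequence[GeneModel],
) -> dict:
    """Headline counts and fractions of the chimeric-transcript catalogue."""
    n_genes = len(genes)
    surviving_tes = [te for te in tes if not te.removed_gene_like]
    n_tes = len(surviving_tes)

    chimeric_transcripts = {c.transcript_id for c in chimeras}
    chimeric_genes = {c.gene_id for c in chimeras}
    chimeric_tes = {c.te_id for c in chimeras}
    event_genes = {e.gene_id for e in events}
    event_tes = {e.te_id for e in events}
    ate_g_isoforms = {e.iso_with for e in events}

    event_hist = {et.value: 0 for et in EventType}
    subtype_hist = {"AFE": 0, "ALE": 0}
    for ev in events:
        event_hist[ev.event.value] += 1
        if ev.subtype is not EventSubtype.NONE:
            subtype_hist[ev.subtype.value] += 1

    position_hist = {"first": 0, "internal": 0, "last": 0}
    for call in chimeras:
        for pos in call.exon_positions:
            position_hist[pos] += 1

    return {
        "n_genes": n_genes,
        "n_tes": n_tes,
        "te_g_transcripts": len(chimeric_transcripts),
        "te_g_pairs": len(chimeras),
        "ate_g_isoforms": len(ate_g_isoforms),
        "ate_g_event_calls": len(events),
        "genes_with_te_g": len(chimeric_genes),
        "tes_in_te_g": len(chimeric_tes),
        "genes_with_ate_g": len(event_genes),
        "tes_in_ate_g": len(event_tes),
        "fraction_genes_te_g": len(chimeric_genes) / n_genes if n_genes else 0.0,
        "fraction_tes_te_g": len(chimeric_tes) / n_tes if n_tes else 0.0,
        "fraction_genes_ate_g": len(event_genes) / n_genes if n_genes else 0.0,
        "fraction_tes_ate_g": len(event_tes) / n_tes if n_tes else 0.0,
        "event_histogram": event_hist,
        "subtype_histogram": subtype_hist,
        "exon_position_histogram": position_hist,
    }
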