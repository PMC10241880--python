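"""Core genomic data model shared by all pipeline stages.

All coordinates are 0-based half-open internally; conversion to the 1-based
closed conventions of GTF/GFF3 happens only at the I/O boundary (see
:mod:`techimera.annotations`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Optional, Sequence


class TELocation(enum.Enum):
    """Genomic location class of a transposable element."""

    UNCLASSIFIED = "unclassified"
    INTERGENIC = "intergenic"
    INTRAGENIC_INTRONIC = "intragenic_intronic"
    INTRAGENIC_EXONIC = "intragenic_exonic"


class EventType(enum.Enum):
    """RNA-processing event relating a pair of isoforms.

    IR/ES/A5SS/A3SS are alternative-splicing events; ATSS/ATTS are
    alternative transcript-production events (start/termination sites).
    """

    IR = "IR"
    ES = "ES"
    A5SS = "A5SS"
    A3SS = "A3SS"
    ATSS = "ATSS"
    ATTS = "ATTS"


class EventSubtype(enum.Enum):
    NONE = "none"
    AFE = "AFE"  # alternative first exon (disjoint first exons; ATSS only)
    ALE = "ALE"  # alternative last exon (disjoint last exons; ATTS only)


#: Alternative-splicing event classes.
AS_EVENTS = frozenset({EventType.IR, EventType.ES, EventType.A5SS, EventType.A3SS})
#: Alternative transcript-production event classes.
ATP_EVENTS = frozenset({EventType.ATSS, EventType.ATTS})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def total_overlap(intervals: Sequence[GenomicInterval], other: GenomicInterval) -> int:
    """Total overlap of ``other`` with a set of non-overlapping intervals."""
    return sum(iv.overlap_bp(other) for iv in intervals)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (strand dropped)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: an ordered exon chain with gene linkage.

    Exons are sorted by start, non-overlapping and all on the same
    chromosome; introns are the gaps between consecutive exons.  The TSS and
    TTS are genomic point coordinates taken strand-aware: on the + strand the
    TSS is the first exon's start; on the - strand it is the last exon's end.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping/unsorted exons"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @cached_property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
            else:
                # zero-length gap: adjacent exons collapse, no intron interval
                raise ValueError(
                    f"transcript {self.transcript_id}: zero-length intron at {a.end}"
                )
        return tuple(out)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """Transcription start site as a genomic point coordinate."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tts(self) -> int:
        """Transcription termination site as a genomic point coordinate."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def first_exon(self) -> GenomicInterval:
        """5'-most exon by transcript strand."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def last_exon(self) -> GenomicInterval:
        """3'-most exon by transcript strand."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def exon_chain_key(self) -> tuple:
        """Hashable identity of the exon chain (used for deduplication)."""
        return (self.chrom, self.strand, tuple((e.start, e.end) for e in self.exons))

    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: one or more transcript isoforms plus a biotype."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @cached_property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        strands = {t.strand for t in self.transcripts}
        strand = strands.pop() if len(strands) == 1 else "."
        return GenomicInterval(self.chrom, start, end, strand)

    @cached_property
    def exonic_union(self) -> tuple[GenomicInterval, ...]:
        """Merged exon intervals across all isoforms."""
        return tuple(merge_intervals(e for t in self.transcripts for e in t.exons))

    def exonic_union_length(self) -> int:
        return sum(iv.length for iv in self.exonic_union)


@dataclass
class TERecord:
    """A transposable-element annotation interval with family labels."""

    te_id: str
    interval: GenomicInterval
    family: str = "Unknown"
    superfamily: str = "Unknown"
    location: TELocation = TELocation.UNCLASSIFIED
    removed_gene_like: bool = False
    host_genes: tuple[str, ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class ChimeraCall:
    """A (transcript, TE) association: the TE overlaps the transcript's exons."""

    transcript_id: str
    gene_id: str
    te_id: str
    overlap_bp: int
    exon_positions: frozenset[str]  # subset of {"first", "internal", "last"}
    te_location: TELocation

    def __post_init__(self) -> None:
        if not self.exon_positions:
            raise ValueError("chimera call with empty exon_positions")
        bad = self.exon_positions - {"first", "internal", "last"}
        if bad:
            raise ValueError(f"invalid exon positions {sorted(bad)}")


@dataclass(frozen=True)
class EventCall:
    """A TE-associated alternative-isoform event at one gene locus."""

    gene_id: str
    te_id: str
    event: EventType
    subtype: EventSubtype
    iso_with: str
    iso_without: str
    region: GenomicInterval
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.subtype is EventSubtype.AFE and self.event is not EventType.ATSS:
            raise ValueError("AFE subtype requires an ATSS event")
        if self.subtype is EventSubtype.ALE and self.event is not EventType.ATTS:
            raise ValueError("ALE subtype requires an ATTS event")
        if self.iso_with == self.iso_without:
            raise ValueError("iso_with and iso_without must differ")
        if self.overlap_bp < 1:
            raise ValueError("event region must overlap its TE by >= 1 bp")


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for TE location classification.

    gene_like_reciprocal_fraction
        A gene is treated as a mis-annotated TE (and dropped together with
        its transcripts) when a TE covers at least this fraction of the
        gene's exonic length *and* the gene span covers the same fraction of
        the TE.
    min_intragenic_overlap_bp
        Minimum span overlap for a TE to count as intragenic.
    exonic_priority
        A TE overlapping exonic bases in any isoform is exonic even if it is
        intronic in other isoforms (keeps intron-retention candidates).
    """

    gene_like_reciprocal_fraction: float = 0.8
    min_intragenic_overlap_bp: int = 1
    exonic_priority: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.gene_like_reciprocal_fraction <= 1):
            raise ValueError("gene_like_reciprocal_fraction must be in (0, 1]")
        if self.min_intragenic_overlap_bp < 1:
            raise ValueError("min_intragenic_overlap_bp must be >= 1")


@dataclass(frozen=True)
class EventConfig:
    """Thresholds for chimera detection and event classification."""

    min_chimera_overlap_bp: int = 10
    atss_min_shift_bp: int = 100
    atts_min_shift_bp: int = 100
    boundary_tolerance_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_chimera_overlap_bp < 1:
            raise ValueError("min_chimera_overlap_bp must be >= 1")
        for name in ("atss_min_shift_bp", "atts_min_shift_bp", "boundary_tolerance_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
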