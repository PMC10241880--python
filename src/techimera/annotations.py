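"""Annotation and sequence I/O.

Readers normalise GTF/GFF3 (1-based closed) and BED (0-based half-open)
records into the internal 0-based half-open model; writers convert back.
Attribute parsing is delegated to :mod:`gffutils`; grouping and validation
happen here so that malformed records are reported with their line number.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import (
    ChimeraCall,
    EventCall,
    GeneModel,
    GenomicInterval,
    TELocation,
    TERecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "GenomeSequence",
    "read_genome",
    "write_genome",
    "read_transcript_annotation",
    "write_transcript_annotation",
    "read_te_annotation",
    "write_te_annotation",
    "write_te_bed",
    "write_results",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


# ---------------------------------------------------------------------------
# genome sequence


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase nucleotide string.

    Out-of-range extraction raises instead of silently clamping, so fixtures
    must pad sequence around any feature whose flanking windows are used.
    """

    _COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

    def __init__(self, sequences: dict[str, str]):
        self._seq = {name: s.upper() for name, s in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seq

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seq)

    def length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end); reverse-complemented when strand is '-'."""
        if chrom not in self._seq:
            raise AnnotationError(f"chromosome {chrom!r} not in genome")
        seq = self._seq[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise AnnotationError(
                f"extraction {chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        s = seq[start:end]
        if strand == "-":
            s = s.translate(self._COMPLEMENT)[::-1]
        return s

    def base_frequencies(self) -> dict[str, float]:
        """Genome-wide A/C/G/T frequencies (N excluded)."""
        counts = {b: 0 for b in "ACGT"}
        for s in self._seq.values():
            for b in "ACGT":
                counts[b] += s.count(b)
        total = sum(counts.values())
        if total == 0:
            raise AnnotationError("genome contains no A/C/G/T bases")
        return {b: c / total for b, c in counts.items()}


def read_genome(path: str | os.PathLike) -> GenomeSequence:
    records = SeqIO.parse(str(path), "fasta")
    return GenomeSequence({rec.id: str(rec.seq) for rec in records})


def write_genome(genome: GenomeSequence, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(genome.fetch(c, 0, genome.length(c))), id=c, description="")
        for c in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# transcript / gene annotation


def _iter_features(path):
    """Yield (line_number, gffutils Feature) skipping comments and blanks."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed column structure
                raise AnnotationError(f"{path}:{lineno}: cannot parse line: {exc}")
            yield lineno, feat


def _single_attr(feat, key: str) -> Optional[str]:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def read_transcript_annotation(
    path: str | os.PathLike,
    dialect: str = "gtf",
    gene_id_key: str = "gene_id",
    transcript_id_key: str = "transcript_id",
    biotype_keys: Sequence[str] = ("gene_biotype", "biotype", "locus_type"),
) -> list[GeneModel]:
    """Read a GTF or GFF3 transcript annotation into gene models.

    GTF exons carry ``gene_id``/``transcript_id`` attributes directly; GFF3
    exons point at their transcript through ``Parent``, and transcript
    features (mRNA/transcript/...) point at their gene.  Transcripts with
    identical exon chains within a gene are collapsed to the first id seen,
    with a logged warning.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")

    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_order: list[str] = []
    gene_biotype: dict[str, str] = {}
    gene_order: list[str] = []

    for lineno, feat in _iter_features(path):
        ftype = feat.featuretype.lower()
        if ftype == "gene":
            gid = (
                _single_attr(feat, "ID")
                or _single_attr(feat, gene_id_key)
                or _single_attr(feat, "Name")
            )
            if gid:
                for key in biotype_keys:
                    bt = _single_attr(feat, key)
                    if bt:
                        gene_biotype[gid] = bt
                        break
            continue
        if ftype in ("mrna", "transcript", "ncrna", "lnc_rna", "mirna"):
            tid = _single_attr(feat, "ID") or _single_attr(feat, transcript_id_key)
            parent = _single_attr(feat, "Parent") or _single_attr(feat, gene_id_key)
            if tid and parent:
                tx_gene.setdefault(tid, parent)
            continue
        if ftype != "exon":
            continue

        if dialect == "gtf":
            tid = _single_attr(feat, transcript_id_key)
            gid = _single_attr(feat, gene_id_key)
            if tid is None:
                raise AnnotationError(
                    f"{path}:{lineno}: exon missing {transcript_id_key!r} attribute"
                )
            if gid is None:
                raise AnnotationError(
                    f"{path}:{lineno}: exon missing {gene_id_key!r} attribute"
                )
            tx_gene.setdefault(tid, gid)
        else:
            tid = _single_attr(feat, "Parent")
            if tid is None:
                raise AnnotationError(f"{path}:{lineno}: exon missing Parent attribute")

        # GTF/GFF3 are 1-based closed; internal model is 0-based half-open
        iv = GenomicInterval(feat.chrom, feat.start - 1, feat.end, feat.strand)
        if tid not in exons:
            tx_order.append(tid)
        exons.setdefault(tid, []).append(iv)

    genes: dict[str, list[TranscriptModel]] = {}
    for tid in tx_order:
        if tid not in tx_gene:
            raise AnnotationError(
                f"{path}: transcript {tid!r} has exons but no gene linkage "
                "(missing mRNA/transcript feature with Parent?)"
            )
        gid = tx_gene[tid]
        ivs = sorted(exons[tid], key=lambda iv: (iv.start, iv.end))
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{path}: transcript {tid!r} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        strand = ivs[0].strand
        tx = TranscriptModel(tid, gid, strand, tuple(ivs))
        if gid not in genes:
            gene_order.append(gid)
        genes.setdefault(gid, []).append(tx)

    out: list[GeneModel] = []
    for gid in gene_order:
        txs = genes[gid]
        seen: dict[tuple, str] = {}
        kept: list[TranscriptModel] = []
        for tx in txs:
            key = tx.exon_chain_key()
            if key in seen:
                logger.warning(
                    "gene %s: transcript %s duplicates exon chain of %s; collapsed",
                    gid,
                    tx.transcript_id,
                    seen[key],
                )
                continue
            seen[key] = tx.transcript_id
            kept.append(tx)
        out.append(
            GeneModel(gid, tuple(kept), biotype=gene_biotype.get(gid, "protein_coding"))
        )
    return out


def write_transcript_annotation(
    genes: Sequence[GeneModel],
    path: str | os.PathLike,
    dialect: str = "gtf",
    source: str = "techimera",
) -> None:
    """Write gene models as GTF or GFF3 (1-based closed coordinates)."""
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines: list[str] = []
    if dialect == "gff3":
        lines.append("##gff-version 3")
    for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        span = gene.span
        if dialect == "gff3":
            lines.append(
                "\t".join(
                    [
                        gene.chrom,
                        source,
                        "gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        span.strand,
                        ".",
                        f"ID={gene.gene_id};biotype={gene.biotype}",
                    ]
                )
            )
        for tx in gene.transcripts:
            tspan = tx.span
            if dialect == "gff3":
                lines.append(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            "mRNA",
                            str(tspan.start + 1),
                            str(tspan.end),
                            ".",
                            tx.strand,
                            ".",
                            f"ID={tx.transcript_id};Parent={gene.gene_id}",
                        ]
                    )
                )
            else:
                lines.append(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            "transcript",
                            str(tspan.start + 1),
                            str(tspan.end),
                            ".",
                            tx.strand,
                            ".",
                            f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                            f'gene_biotype "{gene.biotype}";',
                        ]
                    )
                )
            for i, exon in enumerate(tx.exons, start=1):
                if dialect == "gff3":
                    attrs = f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}"
                else:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'exon_number "{i}";'
                    )
                lines.append(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TE annotation


def read_te_annotation(
    path: str | os.PathLike,
    format: str = "gff3",
    family_key: str = "Alias",
    superfamily_key: str = "Superfamily",
    bed_name_delimiter: str = "|",
) -> list[TERecord]:
    """Read a TE annotation (GFF3 or BED) into TE records.

    GFF3 records take the TE id from ``ID`` (or ``Name``), the family from
    ``family_key`` and the superfamily from ``superfamily_key``.  BED name
    fields are split on ``bed_name_delimiter`` as id|family|superfamily.
    Records lacking a superfamily are kept with superfamily "Unknown"; the
    number of such records is logged.
    """
    tes: list[TERecord] = []
    missing = 0
    if format == "gff3":
        counter = 0
        for lineno, feat in _iter_features(path):
            counter += 1
            te_id = (
                _single_attr(feat, "ID")
                or _single_attr(feat, "Name")
                or f"TE{counter:06d}"
            )
            family = _single_attr(feat, family_key) or "Unknown"
            superfamily = _single_attr(feat, superfamily_key)
            if superfamily is None:
                missing += 1
                superfamily = "Unknown"
            iv = GenomicInterval(feat.chrom, feat.start - 1, feat.end, feat.strand or ".")
            tes.append(TERecord(te_id, iv, family=family, superfamily=superfamily))
    elif format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise AnnotationError(
                        f"{path}:{lineno}: BED TE record needs >= 4 columns"
                    )
                chrom, start, end, name = fields[:4]
                strand = fields[5] if len(fields) >= 6 else "."
                tokens = name.split(bed_name_delimiter)
                te_id = tokens[0]
                family = tokens[1] if len(tokens) > 1 else "Unknown"
                if len(tokens) > 2:
                    superfamily = tokens[2]
                else:
                    missing += 1
                    superfamily = "Unknown"
                iv = GenomicInterval(chrom, int(start), int(end), strand)
                tes.append(TERecord(te_id, iv, family=family, superfamily=superfamily))
    else:
        raise ValueError(f"unknown TE annotation format {format!r}")
    if missing:
        logger.warning("%d TE records lacked a superfamily label", missing)
    return tes


def write_te_annotation(
    tes: Sequence[TERecord],
    path: str | os.PathLike,
    source: str = "techimera",
    family_key: str = "Alias",
    superfamily_key: str = "Superfamily",
) -> None:
    lines = ["##gff-version 3"]
    for te in sorted(tes, key=lambda t: (t.chrom, t.interval.start, t.te_id)):
        iv = te.interval
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    source,
                    "transposable_element",
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    f"ID={te.te_id};{family_key}={te.family};"
                    f"{superfamily_key}={te.superfamily}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_te_bed(
    tes: Sequence[TERecord], path: str | os.PathLike, delimiter: str = "|"
) -> None:
    """BED6 of TEs with id|family|superfamily|location in the name field."""
    lines = []
    for te in sorted(tes, key=lambda t: (t.chrom, t.interval.start, t.te_id)):
        iv = te.interval
        name = delimiter.join(
            [te.te_id, te.family, te.superfamily, te.location.value]
        )
        lines.append(
            "\t".join([iv.chrom, str(iv.start), str(iv.end), name, "0", iv.strand])
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# result tables


@dataclass
class ResultBundle:
    """All tabular outputs of one pipeline run (any subset may be present)."""

    chimeras: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)
    motifs: pd.DataFrame = field(default_factory=pd.DataFrame)
    polya_overlap: pd.DataFrame = field(default_factory=pd.DataFrame)
    methylation: pd.DataFrame = field(default_factory=pd.DataFrame)


_TABLE_COLUMNS = {
    "chimeras.tsv": [
        "transcript_id",
        "gene_id",
        "te_id",
        "overlap_bp",
        "exon_positions",
        "te_location",
    ],
    "events.tsv": [
        "gene_id",
        "te_id",
        "te_superfamily",
        "event",
        "subtype",
        "iso_with",
        "iso_without",
        "chrom",
        "region_start",
        "region_end",
        "strand",
        "overlap_bp",
    ],
    "enrichment.tsv": [
        "category",
        "superfamily",
        "N_total",
        "K_superfamily",
        "n_category",
        "k_observed",
        "expected",
        "fold_enrichment",
        "fold_printed",
        "p_over",
        "p_under",
        "q_over",
        "q_under",
    ],
    "motifs.tsv": [
        "site_type",
        "subset",
        "position",
        "base",
        "count",
        "frequency",
        "background_frequency",
        "fold",
        "p_over",
    ],
    "polya_overlap.tsv": [
        "te_id",
        "chrom",
        "start",
        "end",
        "has_site",
        "n_windows",
        "n_read_3prime",
        "n_database",
    ],
    "methylation.tsv": [
        "te_id",
        "context",
        "covered_cytosines",
        "percent_methylation",
        "delta_vs_control",
    ],
}

_SORT_KEYS = {
    "chimeras.tsv": ["gene_id", "transcript_id", "te_id"],
    "events.tsv": ["chrom", "region_start", "gene_id", "te_id", "event"],
    "enrichment.tsv": ["category", "superfamily"],
    "motifs.tsv": ["site_type", "subset", "position", "base"],
    "polya_overlap.tsv": ["chrom", "start", "te_id"],
    "methylation.tsv": ["te_id", "context"],
}


def write_results(
    bundle: ResultBundle,
    out_dir: str | os.PathLike,
    ate_g_genes: Optional[Sequence[GeneModel]] = None,
    events: Optional[Sequence[EventCall]] = None,
    tes: Optional[Sequence[TERecord]] = None,
) -> list[Path]:
    """Write all result tables to ``out_dir`` with deterministic row order.

    Also writes a GFF3 of ATE-G transcripts annotated with their events (when
    ``ate_g_genes`` and ``events`` are given) and a classified-TE BED (when
    ``tes`` is given).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    frames = {
        "chimeras.tsv": bundle.chimeras,
        "events.tsv": bundle.events,
        "enrichment.tsv": bundle.enrichment,
        "motifs.tsv": bundle.motifs,
        "polya_overlap.tsv": bundle.polya_overlap,
        "methylation.tsv": bundle.methylation,
    }
    for name, df in frames.items():
        cols = _TABLE_COLUMNS[name]
        if df is None or df.empty:
            df = pd.DataFrame(columns=cols)
        else:
            df = df.reindex(columns=cols)
            df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(
                drop=True
            )
        path = out / name
        try:
            df.to_csv(path, sep="\t", index=False)
        except OSError as exc:
            raise AnnotationError(f"cannot write {path}: {exc}")
        written.append(path)

    if tes is not None:
        path = out / "tes_classified.bed"
        write_te_bed(tes, path)
        written.append(path)

    if ate_g_genes is not None and events is not None:
        path = out / "ate_g_transcripts.gff3"
        _write_ate_g_gff3(ate_g_genes, events, path)
        written.append(path)
    return written


def _write_ate_g_gff3(
    genes: Sequence[GeneModel], events: Sequence[EventCall], path: Path
) -> None:
    by_tx: dict[str, list[EventCall]] = {}
    for ev in events:
        by_tx.setdefault(ev.iso_with, []).append(ev)
    lines = ["##gff-version 3"]
    for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        for tx in gene.transcripts:
            evs = by_tx.get(tx.transcript_id)
            if not evs:
                continue
            te_ids = sorted({ev.te_id for ev in evs})
            ev_names = sorted(
                {
                    ev.event.value
                    + ("" if ev.subtype.value == "none" else f":{ev.subtype.value}")
                    for ev in evs
                }
            )
            span = tx.span
            lines.append(
                "\t".join(
                    [
                        tx.chrom,
                        "techimera",
                        "mRNA",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        tx.strand,
                        ".",
                        f"ID={tx.transcript_id};Parent={gene.gene_id};"
                        f"te_id={','.join(te_ids)};events={','.join(ev_names)}",
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")
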