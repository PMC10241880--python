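"""Synthetic genome + annotation generator with planted ground truth.

The generator emits a toy genome (plus an unmethylated control contig), TE
and transcript annotations, poly(A) anchors and a per-cytosine methylation
table, together with a machine-readable truth ledger.  Each gene is built
from a fixed geometric template for one event type (or no event), so that
the identity, region and direction of every planted event are known exactly
and the event classifier can be scored with recall and precision.

Templates are geometry-fixed and unambiguous: every planted intron carries
canonical GT..AG boundary dinucleotides (strand-aware), alternative termini
differ by well over the calling threshold, and decoy structures that could
produce a second event type are avoided by construction.  A ``noise`` mode
adds duplicate isoforms and TE-boundary jitter for robustness testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotations import (
    GenomeSequence,
    write_genome,
    write_te_annotation,
    write_transcript_annotation,
)
from .model import (
    GeneModel,
    GenomicInterval,
    TERecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "simulate_dataset"]

#: Per-gene template window, flanking margin and inter-gene gap (bp).
GENE_WINDOW = 1100
MARGIN = 200
GENE_GAP = 400
GENES_PER_CHROM = 25
CONTROL_CONTIG = "control_mito"

EVENT_KEYS = ("IR", "ES", "A5SS", "A3SS", "ATSS", "AFE", "ATTS", "ALE", "none")

#: TE superfamily vocabulary and default genome-share weights.
DEFAULT_SUPERFAMILY_WEIGHTS = {
    "LTR/Copia": 0.15,
    "LTR/Gypsy": 0.25,
    "TIR/Mutator": 0.15,
    "TIR/CACTA": 0.10,
    "Harbinger": 0.05,
    "Helitron": 0.20,
    "TIR/hAT": 0.10,
}

#: Per-location-class, per-context methylation probabilities.  Event
#: (exonic) TEs are hypomethylated relative to intronic and intergenic TEs,
#: emulating the preferential exonization of epigenetically de-repressed TEs.
DEFAULT_METHYLATION_PROFILES = {
    "intergenic": {"CG": 0.85, "CHG": 0.65, "CHH": 0.30},
    "intragenic_intronic": {"CG": 0.70, "CHG": 0.50, "CHH": 0.20},
    "intragenic_exonic": {"CG": 0.40, "CHG": 0.25, "CHH": 0.10},
}


def _default_event_mix() -> dict[str, int]:
    return {
        "IR": 5,
        "ES": 5,
        "A5SS": 5,
        "A3SS": 5,
        "ATSS": 5,
        "AFE": 5,
        "ATTS": 5,
        "ALE": 5,
        "none": 20,
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    The defaults give 60 genes (40 with one planted event each), 150 TEs,
    an Arabidopsis-like GC content, a 0.5% methylation-calling error rate
    and poly(A) sites planted inside 70% of the alternative-termination TEs.
    """

    seed: int = 0
    n_genes: int = 60
    n_te_total: int = 150
    event_mix: dict[str, int] = field(default_factory=_default_event_mix)
    intergenic_te_fraction: float = 0.3
    superfamily_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPERFAMILY_WEIGHTS)
    )
    genome_gc: float = 0.36
    methylation_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_METHYLATION_PROFILES.items()
        }
    )
    polya_in_atts_fraction: float = 0.7
    error_rate: float = 0.005
    meth_sites_per_te: int = 50
    meth_depth: int = 20
    control_cytosines: int = 2000
    noise: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.event_mix) - set(EVENT_KEYS)
        if unknown:
            raise ValueError(f"unknown event types in mix: {sorted(unknown)}")
        if any(v < 0 for v in self.event_mix.values()):
            raise ValueError("event counts must be >= 0")
        if sum(self.event_mix.values()) > self.n_genes:
            raise ValueError(
                f"event mix requests {sum(self.event_mix.values())} genes "
                f"but n_genes = {self.n_genes}"
            )
        for frac in (
            self.intergenic_te_fraction,
            self.polya_in_atts_fraction,
            self.genome_gc,
        ):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        n_planted = sum(v for k, v in self.event_mix.items() if k != "none")
        if self.n_te_total < n_planted + self.event_mix.get("none", 0):
            raise ValueError("n_te_total too small for the requested event mix")


# ---------------------------------------------------------------------------
# event templates (local 0-based coordinates inside a GENE_WINDOW, + layout)
#
# Each template lists the exon chains of isoform 1/2, the planted TE, the
# expected event region, and which isoform carries the TE-containing form.

_T = {
    "IR": {
        "iso1": [(100, 400), (600, 900)],
        "iso2": [(100, 900)],
        # spans the whole intron incl. both splice sites, as exonized TEs do
        "te": (380, 620),
        "region": (400, 600),
        "event": "IR",
        "subtype": "none",
        "iso_with": 2,
    },
    "ES": {
        "iso1": [(100, 300), (500, 640), (800, 1000)],
        "iso2": [(100, 300), (800, 1000)],
        "te": (520, 620),
        "region": (500, 640),
        "event": "ES",
        "subtype": "none",
        "iso_with": 1,
    },
    "A5SS": {
        "iso1": [(100, 250), (450, 700)],
        "iso2": [(100, 370), (450, 700)],
        "te": (260, 360),
        "region": (250, 370),
        "event": "A5SS",
        "subtype": "none",
        "iso_with": 2,
    },
    "A3SS": {
        "iso1": [(100, 250), (450, 700)],
        "iso2": [(100, 250), (330, 700)],
        "te": (340, 440),
        "region": (330, 450),
        "event": "A3SS",
        "subtype": "none",
        "iso_with": 2,
    },
    "ATSS": {
        "iso1": [(100, 500), (700, 950)],
        "iso2": [(300, 500), (700, 950)],
        "te": (130, 270),
        "region": (100, 300),
        "event": "ATSS",
        "subtype": "none",
        "iso_with": 1,
    },
    "AFE": {
        "iso1": [(100, 250), (600, 900)],
        "iso2": [(350, 500), (600, 900)],
        "te": (110, 240),
        "region": (100, 250),
        "event": "ATSS",
        "subtype": "AFE",
        "iso_with": 1,
    },
    "ATTS": {
        "iso1": [(100, 350), (550, 950)],
        "iso2": [(100, 350), (550, 700)],
        "te": (720, 930),
        "region": (700, 950),
        "event": "ATTS",
        "subtype": "none",
        "iso_with": 1,
    },
    "ALE": {
        "iso1": [(100, 250), (450, 600)],
        "iso2": [(100, 250), (700, 950)],
        "te": (720, 930),
        "region": (700, 950),
        "event": "ATTS",
        "subtype": "ALE",
        "iso_with": 2,
    },
    "none": {
        "iso1": [(100, 400), (600, 900)],
        "iso2": None,
        "te": None,  # chosen per gene (alternating exonic/intronic)
        "region": None,
        "event": "none",
        "subtype": "none",
        "iso_with": 1,
    },
}

_NONE_EXONIC_TE = (150, 260)
_NONE_INTRONIC_TE = (430, 530)
_EXTRA_EXONIC_TE = (650, 740)
_EXTRA_INTRONIC_TE = (540, 590)


def _mirror(iv: tuple[int, int]) -> tuple[int, int]:
    return (GENE_WINDOW - iv[1], GENE_WINDOW - iv[0])


def _place(iv: tuple[int, int], strand: str, offset: int) -> tuple[int, int]:
    if strand == "-":
        iv = _mirror(iv)
    return (iv[0] + offset, iv[1] + offset)


@dataclass
class SimulatedDataset:
    """In-memory fixture: annotations, sequences, tables and ground truth."""

    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    tes: list[TERecord]
    truth: pd.DataFrame
    polya_anchors: list[GenomicInterval]
    cytosines: pd.DataFrame
    te_true_location: dict[str, str]


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Build the full synthetic dataset in memory, deterministically."""
    rng = np.random.default_rng(cfg.seed)

    # --- gene labels -------------------------------------------------------
    labels: list[str] = []
    for key in EVENT_KEYS:
        if key != "none":
            labels.extend([key] * cfg.event_mix.get(key, 0))
    labels.extend(["none"] * (cfg.n_genes - len(labels)))
    rng.shuffle(labels)

    n_chroms = (cfg.n_genes + GENES_PER_CHROM - 1) // GENES_PER_CHROM
    stride = GENE_WINDOW + GENE_GAP
    chrom_len = MARGIN + GENES_PER_CHROM * stride + MARGIN

    genes: list[GeneModel] = []
    tes: list[TERecord] = []
    te_true_location: dict[str, str] = {}
    truth_rows: list[dict] = []
    planted_introns: list[tuple[str, int, int, str]] = []
    polya_anchors: list[GenomicInterval] = []
    superfams = sorted(cfg.superfamily_weights)
    sf_weights = np.array([cfg.superfamily_weights[s] for s in superfams], dtype=float)
    sf_weights = sf_weights / sf_weights.sum()

    te_counter = 0

    def new_te(chrom, start, end, location_class) -> TERecord:
        nonlocal te_counter
        te_counter += 1
        sf = superfams[int(rng.choice(len(superfams), p=sf_weights))]
        te_id = f"TE{te_counter:05d}"
        family = f"{sf.split('/')[-1].upper()}_{te_counter:05d}"
        te_true_location[te_id] = location_class
        return TERecord(
            te_id,
            GenomicInterval(chrom, start, end, "."),
            family=family,
            superfamily=sf,
        )

    none_gene_slots: list[tuple[str, str, int]] = []  # (chrom, strand, offset)

    for gi, label in enumerate(labels):
        chrom = f"chr{gi // GENES_PER_CHROM + 1}"
        offset = MARGIN + (gi % GENES_PER_CHROM) * stride
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{gi + 1:04d}"
        tmpl = _T[label]

        transcripts = []
        for iso_idx, key in ((1, "iso1"), (2, "iso2")):
            chain = tmpl[key]
            if chain is None:
                continue
            exons = sorted(_place(e, strand, offset) for e in chain)
            transcripts.append(
                TranscriptModel(
                    f"{gene_id}.{iso_idx}",
                    gene_id,
                    strand,
                    tuple(
                        GenomicInterval(chrom, s, e, strand) for s, e in exons
                    ),
                )
            )
        gene = GeneModel(gene_id, tuple(transcripts))
        genes.append(gene)

        for tx in transcripts:
            for intron in tx.introns:
                planted_introns.append((chrom, intron.start, intron.end, strand))

        if label == "none":
            none_gene_slots.append((chrom, strand, offset))
            none_idx = len(none_gene_slots) - 1
            te_local = _NONE_EXONIC_TE if none_idx % 2 == 0 else _NONE_INTRONIC_TE
            loc = (
                "intragenic_exonic"
                if none_idx % 2 == 0
                else "intragenic_intronic"
            )
            s, e = _place(te_local, strand, offset)
            tes.append(new_te(chrom, s, e, loc))
            continue

        te_s, te_e = _place(tmpl["te"], strand, offset)
        te = new_te(chrom, te_s, te_e, "intragenic_exonic")
        tes.append(te)
        reg_s, reg_e = _place(tmpl["region"], strand, offset)
        expected_event = tmpl["event"]
        expected_subtype = tmpl["subtype"]
        iso_with = f"{gene_id}.{tmpl['iso_with']}"
        iso_without = f"{gene_id}.{3 - tmpl['iso_with']}"

        polya_planted = False
        if expected_event == "ATTS":
            if rng.random() < cfg.polya_in_atts_fraction:
                polya_planted = True
                mid = (te_s + te_e) // 2
                polya_anchors.append(GenomicInterval(chrom, mid, mid + 1, strand))
            else:
                # anchor well outside the TE so the gene still terminates
                polya_anchors.append(
                    GenomicInterval(chrom, offset + GENE_WINDOW + 50,
                                    offset + GENE_WINDOW + 51, strand)
                )

        truth_rows.append(
            {
                "gene_id": gene_id,
                "te_id": te.te_id,
                "planted": label,
                "event": expected_event,
                "subtype": expected_subtype,
                "iso_with": iso_with,
                "iso_without": iso_without,
                "chrom": chrom,
                "region_start": reg_s,
                "region_end": reg_e,
                "polya_planted": polya_planted,
            }
        )

    # background poly(A) anchors at the 3' end of event-free genes
    for chrom, strand, offset in none_gene_slots:
        tts_local = 900 if strand == "+" else GENE_WINDOW - 900
        pos = offset + tts_local
        polya_anchors.append(GenomicInterval(chrom, pos, pos + 1, strand))

    # --- extra TEs ---------------------------------------------------------
    n_extra = cfg.n_te_total - len(tes)
    n_intergenic = int(round(n_extra * cfg.intergenic_te_fraction))
    n_intragenic = n_extra - n_intergenic
    if not none_gene_slots:
        n_intergenic, n_intragenic = n_extra, 0

    placed = 0
    slot = 0
    while placed < n_intragenic and none_gene_slots:
        chrom, strand, offset = none_gene_slots[slot % len(none_gene_slots)]
        # two safe slots per event-free gene: one exonic, one intronic
        which = slot // len(none_gene_slots)
        if which >= 2:
            break
        local = _EXTRA_EXONIC_TE if which == 0 else _EXTRA_INTRONIC_TE
        loc = "intragenic_exonic" if which == 0 else "intragenic_intronic"
        s, e = _place(local, strand, offset)
        tes.append(new_te(chrom, s, e, loc))
        placed += 1
        slot += 1
    n_intergenic += n_intragenic - placed

    for _ in range(n_intergenic):
        gi = int(rng.integers(0, cfg.n_genes))
        chrom = f"chr{gi // GENES_PER_CHROM + 1}"
        gap_start = MARGIN + (gi % GENES_PER_CHROM) * stride + GENE_WINDOW
        length = int(rng.integers(100, 350))
        start = gap_start + int(rng.integers(10, GENE_GAP - length - 10))
        tes.append(new_te(chrom, start, start + length, "intergenic"))

    # --- genome sequence ---------------------------------------------------
    gc = cfg.genome_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    seq_arrays: dict[str, np.ndarray] = {}
    for c in range(n_chroms):
        name = f"chr{c + 1}"
        seq_arrays[name] = rng.choice(bases, size=chrom_len, p=probs)
    for chrom, s, e, strand in planted_introns:
        arr = seq_arrays[chrom]
        if strand == "+":
            arr[s], arr[s + 1] = "G", "T"
            arr[e - 2], arr[e - 1] = "A", "G"
        else:
            arr[s], arr[s + 1] = "C", "T"
            arr[e - 2], arr[e - 1] = "A", "C"
    for name, arr in seq_arrays.items():
        sequences[name] = "".join(arr)
    ctrl_len = cfg.control_cytosines + 10
    sequences[CONTROL_CONTIG] = "".join(
        rng.choice(bases, size=ctrl_len, p=probs)
    )
    genome = GenomeSequence(sequences)

    # --- methylation table -------------------------------------------------
    cyto_rows: list[tuple] = []
    contexts = ("CG", "CHG", "CHH")
    for te in tes:
        profile = cfg.methylation_profiles[te_true_location[te.te_id]]
        iv = te.interval
        n_sites = min(cfg.meth_sites_per_te, iv.length)
        positions = np.linspace(iv.start, iv.end - 1, n_sites).astype(int)
        positions = np.unique(positions)
        for i, pos in enumerate(positions):
            context = contexts[i % 3]
            p = profile[context]
            n_meth = int(rng.binomial(cfg.meth_depth, p))
            cyto_rows.append(
                (
                    iv.chrom,
                    int(pos),
                    "+" if i % 2 == 0 else "-",
                    context,
                    n_meth,
                    cfg.meth_depth - n_meth,
                )
            )
    for i in range(cfg.control_cytosines):
        context = contexts[i % 3]
        n_meth = int(rng.binomial(cfg.meth_depth, cfg.error_rate))
        cyto_rows.append(
            (
                CONTROL_CONTIG,
                i,
                "+" if i % 2 == 0 else "-",
                context,
                n_meth,
                cfg.meth_depth - n_meth,
            )
        )
    cytosines = pd.DataFrame(
        cyto_rows,
        columns=["chrom", "pos", "strand", "context", "count_meth", "count_unmeth"],
    )

    # --- noise mode --------------------------------------------------------
    if cfg.noise:
        noisy_genes = []
        for gene in genes:
            if len(gene.transcripts) >= 2 and rng.random() < 0.3:
                dup = gene.transcripts[0]
                extra = TranscriptModel(
                    dup.transcript_id + "_dup",
                    gene.gene_id,
                    dup.strand,
                    dup.exons,
                )
                noisy_genes.append(
                    GeneModel(
                        gene.gene_id, gene.transcripts + (extra,), gene.biotype
                    )
                )
            else:
                noisy_genes.append(gene)
        genes = noisy_genes

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "te_id",
            "planted",
            "event",
            "subtype",
            "iso_with",
            "iso_without",
            "chrom",
            "region_start",
            "region_end",
            "polya_planted",
        ],
    )
    return SimulatedDataset(
        config=cfg,
        genome=genome,
        genes=genes,
        tes=tes,
        truth=truth,
        polya_anchors=polya_anchors,
        cytosines=cytosines,
        te_true_location=te_true_location,
    )


def simulate_dataset(cfg: SimulationConfig, out_dir) -> dict[str, Path]:
    """Simulate and write the full fixture file set; returns the paths.

    Files: genome.fa (with the unmethylated control contig), transcripts.gtf,
    tes.gff3, polya.bed, cytosines.tsv and truth.tsv.  Byte-identical across
    runs with the same config.
    """
    ds = simulate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "transcripts": out / "transcripts.gtf",
        "tes": out / "tes.gff3",
        "polya": out / "polya.bed",
        "cytosines": out / "cytosines.tsv",
        "truth": out / "truth.tsv",
    }
    write_genome(ds.genome, paths["genome"])
    write_transcript_annotation(ds.genes, paths["transcripts"], dialect="gtf")
    write_te_annotation(ds.tes, paths["tes"])
    lines = [
        "\t".join(
            [a.chrom, str(a.start), str(a.end), f"pa{i + 1}", "1", a.strand]
        )
        for i, a in enumerate(ds.polya_anchors)
    ]
    paths["polya"].write_text("\n".join(lines) + "\n" if lines else "")
    ds.cytosines.to_csv(paths["cytosines"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
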