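"""Annotation I/O: coordinate conventions, grouping, round trips."""

import pandas as pd
import pytest

from techimera.annotations import (
    AnnotationError,
    ResultBundle,
    read_te_annotation,
    read_transcript_annotation,
    write_results,
    write_te_annotation,
    write_te_bed,
    write_transcript_annotation,
)
from techimera.model import GenomicInterval, TELocation, TERecord
from techimera.simulate import SimulationConfig, simulate

from conftest import make_gene, make_te, make_tx


GTF_TWO_TX = """\
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
"""


def test_gtf_grouping_and_intron_counts(tmp_path):
    p = tmp_path / "in.gtf"
    p.write_text(GTF_TWO_TX)
    genes = read_transcript_annotation(p, dialect="gtf")
    assert len(genes) == 1
    gene = genes[0]
    assert {t.transcript_id for t in gene.transcripts} == {"t1", "t2"}
    by_id = {t.transcript_id: t for t in gene.transcripts}
    assert len(by_id["t1"].exons) == 3 and len(by_id["t1"].introns) == 2
    assert len(by_id["t2"].exons) == 2 and len(by_id["t2"].introns) == 1


def test_gff3_coordinate_conversion(tmp_path):
    p = tmp_path / "in.gff3"
    p.write_text(
        "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=t1\n"
    )
    genes = read_transcript_annotation(p, dialect="gff3")
    exon = genes[0].transcripts[0].exons[0]
    assert (exon.start, exon.end, exon.length) == (100, 200, 100)


@pytest.mark.parametrize("dialect", ["gtf", "gff3"])
def test_transcript_round_trip_on_simulated_annotation(tmp_path, dialect):
    """write -> read is the identity on a simulated 50-gene model."""
    mix = {"IR": 5, "ES": 5, "A5SS": 5, "A3SS": 5, "ATSS": 5, "AFE": 5,
           "ATTS": 5, "ALE": 5, "none": 10}
    ds = simulate(SimulationConfig(seed=11, n_genes=50, n_te_total=60, event_mix=mix))
    p = tmp_path / f"rt.{dialect}"
    write_transcript_annotation(ds.genes, p, dialect=dialect)
    back = read_transcript_annotation(p, dialect=dialect)
    orig = {g.gene_id: g for g in ds.genes}
    assert set(orig) == {g.gene_id for g in back}
    for g in back:
        o = orig[g.gene_id]
        assert {t.transcript_id: t.exon_chain_key() for t in g.transcripts} == {
            t.transcript_id: t.exon_chain_key() for t in o.transcripts
        }


def test_te_bed_and_gff3_parsing(tmp_path):
    bed = tmp_path / "te.bed"
    bed.write_text("Chr1\t1000\t2000\tAT1TE001|ATCOPIA78|LTR/Copia\t0\t+\n")
    (te,) = read_te_annotation(bed, format="bed")
    assert te.te_id == "AT1TE001"
    assert te.family == "ATCOPIA78"
    assert te.superfamily == "LTR/Copia"
    assert (te.interval.start, te.interval.end) == (1000, 2000)

    gff = tmp_path / "te.gff3"
    gff.write_text(
        "Chr1\tsrc\ttransposable_element\t1001\t2000\t.\t+\t.\t"
        "ID=AT1TE001;Alias=ATCOPIA4;Superfamily=LTR/Copia\n"
    )
    (te2,) = read_te_annotation(gff, format="gff3")
    assert te2.superfamily == "LTR/Copia"
    assert te2.family == "ATCOPIA4"
    assert (te2.interval.start, te2.interval.end) == (1000, 2000)


def test_te_missing_superfamily_kept_as_unknown(tmp_path):
    gff = tmp_path / "te.gff3"
    gff.write_text("Chr1\tsrc\ttransposable_element\t10\t50\t.\t+\t.\tID=TE1\n")
    (te,) = read_te_annotation(gff, format="gff3")
    assert te.superfamily == "Unknown"


def test_te_round_trip(tmp_path):
    ds = simulate(SimulationConfig(seed=5, n_te_total=120))
    p = tmp_path / "tes.gff3"
    write_te_annotation(ds.tes, p)
    back = read_te_annotation(p, format="gff3")
    orig = {t.te_id: t for t in ds.tes}
    assert len(back) == len(ds.tes)
    for te in back:
        o = orig[te.te_id]
        assert te.interval == o.interval
        assert te.superfamily == o.superfamily
        assert te.family == o.family


def test_duplicate_exon_chains_collapsed(tmp_path, caplog):
    p = tmp_path / "dup.gtf"
    p.write_text(
        'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t2";\n'
    )
    with caplog.at_level("WARNING"):
        genes = read_transcript_annotation(p)
    assert len(genes[0].transcripts) == 1
    assert genes[0].transcripts[0].transcript_id == "t1"
    assert "duplicates exon chain" in caplog.text


def test_missing_transcript_id_names_line_number(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text(
        'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        'chr1\ts\texon\t200\t300\t.\t+\t.\tgene_id "g";\n'
    )
    with pytest.raises(AnnotationError, match=":2"):
        read_transcript_annotation(p)


def test_overlapping_exons_rejected(tmp_path):
    p = tmp_path / "ovl.gtf"
    p.write_text(
        'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\ts\texon\t50\t150\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    )
    with pytest.raises(AnnotationError, match="overlapping exons"):
        read_transcript_annotation(p)


def test_one_bp_feature_conventions(tmp_path):
    """A 1-bp feature is GFF3 start==end and BED end==start+1."""
    te = make_te("te1", 41, 42)
    gff = tmp_path / "one.gff3"
    write_te_annotation([te], gff)
    line = [l for l in gff.read_text().splitlines() if not l.startswith("#")][0]
    fields = line.split("\t")
    assert (fields[3], fields[4]) == ("42", "42")

    bed = tmp_path / "one.bed"
    write_te_bed([te], bed)
    fields = bed.read_text().split("\t")
    assert (fields[1], fields[2]) == ("41", "42")
    (back,) = read_te_annotation(gff, format="gff3")
    assert (back.interval.start, back.interval.end) == (41, 42)


def test_write_results_empty_and_deterministic(tmp_path):
    out1 = tmp_path / "r1"
    out2 = tmp_path / "r2"
    bundle = ResultBundle()
    write_results(bundle, out1)
    events = (out1 / "events.tsv").read_text().splitlines()
    assert len(events) == 1 and events[0].startswith("gene_id\t")

    df = pd.DataFrame(
        [
            {"gene_id": "g2", "te_id": "b", "event": "IR", "chrom": "chr1",
             "region_start": 5, "region_end": 9},
            {"gene_id": "g1", "te_id": "a", "event": "ES", "chrom": "chr1",
             "region_start": 1, "region_end": 4},
        ]
    )
    bundle2 = ResultBundle(events=df)
    write_results(bundle2, out1)
    write_results(bundle2, out2)
    assert (out1 / "events.tsv").read_bytes() == (out2 / "events.tsv").read_bytes()
    rows = (out1 / "events.tsv").read_text().splitlines()[1:]
    assert rows[0].split("\t")[0] == "g1"  # sorted by coordinate then ids
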