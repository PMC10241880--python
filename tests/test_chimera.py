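"""Chimera calling and pairwise isoform-event classification."""

import numpy as np
import pytest

from techimera.chimera import (
    _pair_events,
    call_ate_g_isoforms,
    detect_te_g_transcripts,
    enumerate_pairwise_events,
    summarize_catalog,
)
from techimera.model import (
    EventConfig,
    EventSubtype,
    EventType,
    GenomicInterval,
    TELocation,
)

from _oracles import oracle_exonic_overlap, random_instance
from conftest import make_gene, make_te, make_tx, mirror_gene, mirror_te

CFG = EventConfig()


def events_of(gene, cfg=CFG):
    return {
        (e.event, e.subtype, e.region.start, e.region.end, e.iso_with, e.iso_without)
        for e in enumerate_pairwise_events(gene, cfg)
    }


# ---------------------------------------------------------------------------
# chimera detection


def test_intronic_te_yields_no_chimera():
    gene = make_gene([make_tx("t1", [(0, 100), (200, 300)])])
    te = make_te("te1", 120, 180)
    assert detect_te_g_transcripts([gene], [te], CFG) == []


def test_last_exon_chimera_and_overlap():
    gene = make_gene([make_tx("t1", [(50, 120), (180, 300)])])
    te = make_te("te1", 180, 300)
    (call,) = detect_te_g_transcripts([gene], [te], CFG)
    assert call.overlap_bp == 120
    assert call.exon_positions == frozenset({"last"})


def test_te_spanning_first_two_exons():
    gene = make_gene([make_tx("t1", [(0, 100), (200, 300), (400, 500)])])
    te = make_te("te1", 50, 250)
    (call,) = detect_te_g_transcripts([gene], [te], CFG)
    assert call.exon_positions == frozenset({"first", "internal"})
    assert call.overlap_bp == 100


def test_exon_positions_follow_strand():
    gene = make_gene([make_tx("t1", [(0, 100), (200, 300)], strand="-")])
    te = make_te("te1", 0, 100)
    (call,) = detect_te_g_transcripts([gene], [te], CFG)
    # leftmost exon is the last exon of a - strand transcript
    assert call.exon_positions == frozenset({"last"})


def test_min_overlap_threshold():
    gene = make_gene([make_tx("t1", [(0, 100)])])
    te = make_te("te1", 95, 200)  # 5 bp < default 10
    assert detect_te_g_transcripts([gene], [te], CFG) == []
    assert len(detect_te_g_transcripts([gene], [te], EventConfig(min_chimera_overlap_bp=5))) == 1


def test_removed_gene_like_te_excluded():
    gene = make_gene([make_tx("t1", [(0, 100)])])
    te = make_te("te1", 0, 100, removed_gene_like=True)
    assert detect_te_g_transcripts([gene], [te], CFG) == []


@pytest.mark.parametrize("seed", range(4))
def test_exonic_overlap_matches_per_base_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    genes, tes, chrom_len = random_instance(rng, max_genes=10, max_tes=40)
    cfg = EventConfig(min_chimera_overlap_bp=1)
    calls = {
        (c.transcript_id, c.te_id): c.overlap_bp
        for c in detect_te_g_transcripts(genes, tes, cfg)
    }
    L = chrom_len["chrT"]
    for gene in genes:
        for tx in gene.transcripts:
            for te in tes:
                expected = oracle_exonic_overlap(tx, te, L)
                got = calls.get((tx.transcript_id, te.te_id), 0)
                assert got == expected


# ---------------------------------------------------------------------------
# pairwise events


def test_textbook_intron_retention(two_isoform_ir_gene):
    evs = enumerate_pairwise_events(two_isoform_ir_gene, CFG)
    assert len(evs) == 1
    ev = evs[0]
    assert ev.event is EventType.IR
    assert (ev.region.start, ev.region.end) == (100, 200)
    assert ev.iso_with == "t.b"  # the retaining isoform


def test_textbook_exon_skipping():
    a = make_tx("a", [(0, 100), (150, 250), (300, 400)])
    b = make_tx("b", [(0, 100), (300, 400)])
    evs = enumerate_pairwise_events(make_gene([a, b]), CFG)
    assert len(evs) == 1
    ev = evs[0]
    assert ev.event is EventType.ES
    assert (ev.region.start, ev.region.end) == (150, 250)
    assert ev.iso_with == "a"  # the including isoform


def test_alternative_donor_site():
    a = make_tx("a", [(0, 100), (200, 300)])
    b = make_tx("b", [(0, 130), (200, 300)])
    evs = enumerate_pairwise_events(make_gene([a, b]), CFG)
    assert len(evs) == 1
    ev = evs[0]
    assert ev.event is EventType.A5SS
    assert (ev.region.start, ev.region.end) == (100, 130)
    assert ev.iso_with == "b"  # exon extends into the region


def test_alternative_acceptor_site_minus_strand():
    # on the - strand the acceptor is the intron's left junction
    a = make_tx("a", [(0, 100), (200, 300)], strand="-")
    b = make_tx("b", [(0, 130), (200, 300)], strand="-")
    evs = enumerate_pairwise_events(make_gene([a, b]), CFG)
    assert len(evs) == 1
    assert evs[0].event is EventType.A3SS


def test_atss_with_afe_subtype():
    a = make_tx("a", [(0, 100), (600, 800)])
    b = make_tx("b", [(500, 550), (600, 800)])
    evs = enumerate_pairwise_events(make_gene([a, b]), CFG)
    assert len(evs) == 1
    ev = evs[0]
    assert ev.event is EventType.ATSS
    assert ev.subtype is EventSubtype.AFE
    assert ev.iso_with == "a"
    assert (ev.region.start, ev.region.end) == (0, 100)


def test_atss_shift_below_threshold_not_called():
    a = make_tx("a", [(0, 300), (500, 700)])
    b = make_tx("b", [(50, 300), (500, 700)])
    assert enumerate_pairwise_events(make_gene([a, b]), CFG) == []
    evs = enumerate_pairwise_events(
        make_gene([a, b]), EventConfig(atss_min_shift_bp=50)
    )
    assert [e.event for e in evs] == [EventType.ATSS]


def test_atts_region_clipped_to_extending_isoform():
    a = make_tx("a", [(0, 200), (400, 700)])
    b = make_tx("b", [(0, 200), (400, 500)])
    evs = enumerate_pairwise_events(make_gene([a, b]), CFG)
    assert len(evs) == 1
    ev = evs[0]
    assert ev.event is EventType.ATTS
    assert ev.subtype is EventSubtype.NONE
    assert (ev.region.start, ev.region.end) == (500, 700)
    assert ev.iso_with == "a"


def test_skipped_exon_does_not_masquerade_as_a3ss():
    """The alternative-acceptor rule must not fire across a skipped exon."""
    a = make_tx("a", [(0, 200), (400, 500), (700, 900)])
    b = make_tx("b", [(0, 200), (700, 900)])
    evs = enumerate_pairwise_events(make_gene([a, b]), CFG)
    assert {e.event for e in evs} == {EventType.ES}


def test_unstranded_pair_skipped(caplog):
    a = make_tx("a", [(0, 100), (200, 300)], strand=".")
    b = make_tx("b", [(0, 300)], strand=".")
    with caplog.at_level("WARNING"):
        evs = enumerate_pairwise_events(make_gene([a, b]), CFG)
    assert evs == []
    assert "unstranded" in caplog.text


def test_pair_symmetry():
    """Events are identical regardless of the order the pair is given in."""
    a = make_tx("a", [(0, 100), (200, 300), (500, 800)])
    b = make_tx("b", [(0, 130), (200, 800)])
    ab = _pair_events(a, b, CFG)
    ba = _pair_events(b, a, CFG)
    key = lambda evs: {
        (e.event, e.subtype, e.region, e.iso_with, e.iso_without) for e in evs
    }
    assert key(ab) == key(ba)


def _gene_with_all_features():
    a = make_tx("a", [(100, 250), (450, 700), (900, 1000)])
    b = make_tx("b", [(100, 370), (450, 700), (900, 1000)])
    c = make_tx("c", [(100, 250), (450, 1000)])
    return make_gene([a, b, c])


def test_mirror_plus_strand_flip_preserves_events():
    """Reversing coordinates and flipping strand relabels but keeps events."""
    gene = _gene_with_all_features()
    L = 1200
    mirrored = mirror_gene(gene, L, flip_strand=True)
    orig = events_of(gene)
    mir = events_of(mirrored)
    remapped = {
        (ev, sub, L - e, L - s, iw, iwo) for (ev, sub, s, e, iw, iwo) in mir
    }
    assert remapped == orig


def test_mirror_without_flip_swaps_donor_acceptor_roles():
    """Coordinate reversal alone exchanges A5SS<->A3SS and ATSS<->ATTS."""
    gene = _gene_with_all_features()
    L = 1200
    mirrored = mirror_gene(gene, L, flip_strand=False)
    swap = {
        EventType.A5SS: EventType.A3SS,
        EventType.A3SS: EventType.A5SS,
        EventType.ATSS: EventType.ATTS,
        EventType.ATTS: EventType.ATSS,
        EventType.IR: EventType.IR,
        EventType.ES: EventType.ES,
    }
    orig = {(swap[ev], s, e) for (ev, _, s, e, _, _) in events_of(gene)}
    mir = {(ev, L - e, L - s) for (ev, _, s, e, _, _) in events_of(mirrored)}
    assert mir == orig


# ---------------------------------------------------------------------------
# TE association and summary


def test_event_call_requires_te_in_region(two_isoform_ir_gene):
    te_in = make_te("te_in", 130, 170)
    te_out = make_te("te_out", 210, 290)
    chim = detect_te_g_transcripts([two_isoform_ir_gene], [te_in, te_out], CFG)
    calls = call_ate_g_isoforms(chim, [two_isoform_ir_gene], [te_in, te_out], CFG)
    assert [c.te_id for c in calls] == ["te_in"]
    assert calls[0].event is EventType.IR
    assert calls[0].overlap_bp == 40


def test_event_region_always_overlaps_te():
    rng = np.random.default_rng(7)
    genes, tes, _ = random_instance(rng, max_genes=12, max_tes=40)
    chim = detect_te_g_transcripts(genes, tes, CFG)
    tx_gene = {t.transcript_id: g.gene_id for g in genes for t in g.transcripts}
    for call in call_ate_g_isoforms(chim, genes, tes, CFG):
        te = next(t for t in tes if t.te_id == call.te_id)
        assert call.region.overlap_bp(te.interval) >= 1
        assert tx_gene[call.iso_with] == call.gene_id
        assert tx_gene[call.iso_without] == call.gene_id


def test_summary_fractions():
    genes = [
        make_gene([make_tx(f"g{i}.1", [(0, 100)], gene_id=f"g{i}")], gene_id=f"g{i}")
        for i in range(10)
    ]
    tes = [make_te(f"te{i}", 0, 100) for i in range(4)]
    chim = [
        c
        for i in range(4)
        for c in detect_te_g_transcripts([genes[i]], [tes[i]], CFG)
    ]
    summary = summarize_catalog(chim, [], tes, genes)
    assert summary["fraction_genes_te_g"] == pytest.approx(0.4)
    assert summary["tes_in_te_g"] <= summary["te_g_pairs"]
    for key in ("fraction_genes_te_g", "fraction_tes_te_g",
                "fraction_genes_ate_g", "fraction_tes_ate_g"):
        assert 0.0 <= summary[key] <= 1.0


def test_empty_inputs_all_zero_summary():
    summary = summarize_catalog([], [], [], [])
    assert summary["te_g_transcripts"] == 0
    assert summary["ate_g_isoforms"] == 0
    assert all(v == 0 for v in summary["event_histogram"].values())
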