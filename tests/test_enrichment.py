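"""Superfamily enrichment statistics and splice-site motif windows."""

import math

import numpy as np
import pytest

from techimera.annotations import GenomeSequence
from techimera.chimera import call_ate_g_isoforms, detect_te_g_transcripts
from techimera.enrichment import (
    SPLICE_WINDOW_FLANK,
    SpliceSiteWindow,
    extract_ir_splice_sites,
    position_nucleotide_enrichment,
    superfamily_enrichment,
    window_fasta,
)
from techimera.model import (
    EventCall,
    EventConfig,
    EventSubtype,
    EventType,
    GenomicInterval,
)
from techimera.pipeline import run_pipeline
from techimera.simulate import SimulationConfig, simulate

from conftest import make_gene, make_te, make_tx


def exact_tails(N, K, n, k):
    """Upper/lower hypergeometric tails by integer pmf summation."""
    denom = math.comb(N, n)
    lo, hi = max(0, n - (N - K)), min(K, n)
    p_over = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, hi + 1))
    p_under = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(lo, k + 1))
    return p_over / denom, p_under / denom


def _fixture(N, K, n, k):
    """TEs and events realising one (N, K, n, k) configuration."""
    tes = [
        make_te(f"te{i}", 100 * i, 100 * i + 50,
                superfamily="LTR/Copia" if i < K else "Other")
        for i in range(N)
    ]
    # the category draws k TEs from the superfamily then fills up to n
    chosen = [f"te{i}" for i in range(k)] + [f"te{K + i}" for i in range(n - k)]
    events = [
        EventCall(
            gene_id=f"g{i}",
            te_id=tid,
            event=EventType.IR,
            subtype=EventSubtype.NONE,
            iso_with=f"g{i}.1",
            iso_without=f"g{i}.2",
            region=GenomicInterval("chr1", 0, 10, "+"),
            overlap_bp=5,
        )
        for i, tid in enumerate(chosen)
    ]
    return tes, events


@pytest.mark.parametrize(
    "N,K,n,k",
    [(100, 10, 10, 1), (20, 5, 4, 4), (50, 25, 10, 3), (30, 6, 12, 0)],
)
def test_hypergeometric_tails_match_exact_summation(N, K, n, k):
    tes, events = _fixture(N, K, n, k)
    results = {r.superfamily: r for r in superfamily_enrichment(tes, events, "IR")}
    r = results["LTR/Copia"]
    p_over, p_under = exact_tails(N, K, n, k)
    assert r.k_observed == k
    assert r.expected == pytest.approx(K * n / N)
    assert r.p_over == pytest.approx(p_over, rel=1e-9)
    assert r.p_under == pytest.approx(p_under, rel=1e-9)


def test_reference_tail_values():
    # N=100, K=10, n=10, k=1: P(X>=1) = 1 - C(90,10)/C(100,10)
    tes, events = _fixture(100, 10, 10, 1)
    r = {x.superfamily: x for x in superfamily_enrichment(tes, events, "IR")}["LTR/Copia"]
    assert r.expected == pytest.approx(1.0)
    assert r.fold_enrichment == pytest.approx(1.0)
    assert r.p_over == pytest.approx(0.6695, abs=5e-4)
    # N=20, K=5, n=4, k=4: C(5,4)*C(15,0)/C(20,4) = 5/4845
    tes, events = _fixture(20, 5, 4, 4)
    r = {x.superfamily: x for x in superfamily_enrichment(tes, events, "IR")}["LTR/Copia"]
    assert r.p_over == pytest.approx(5 / 4845, rel=1e-9)


def test_degenerate_population_fold_one():
    tes, events = _fixture(15, 15, 6, 6)  # K = N, k = n
    (r,) = superfamily_enrichment(tes, events, "IR")
    assert r.fold_enrichment == pytest.approx(1.0)
    assert r.p_over == pytest.approx(1.0)


def test_tail_identity_and_conservation():
    tes, events = _fixture(40, 12, 15, 7)
    results = superfamily_enrichment(tes, events, "IR")
    n_cat = results[0].n_category
    assert sum(r.k_observed for r in results) == n_cat
    assert sum(r.expected for r in results) == pytest.approx(n_cat)
    for r in results:
        p_over, p_under = exact_tails(r.N_total, r.K_superfamily, n_cat, r.k_observed)
        pmf = p_over + p_under - 1.0
        assert r.p_over + r.p_under - pmf == pytest.approx(1.0, abs=1e-9)


def test_empty_category_returns_empty():
    tes, events = _fixture(10, 3, 4, 2)
    assert superfamily_enrichment(tes, events, "ES") == []


def test_printed_fold_is_inverse():
    tes, events = _fixture(60, 12, 10, 6)
    r = {x.superfamily: x for x in superfamily_enrichment(tes, events, "IR")}["LTR/Copia"]
    assert r.fold_printed == pytest.approx(1.0 / r.fold_enrichment)


def test_random_category_mean_fold_near_one():
    """Uniformly random category membership gives mean fold ~ 1."""
    rng = np.random.default_rng(42)
    N, n = 150, 40
    superfams = ["A", "B", "C", "D"]
    tes = [
        make_te(f"te{i}", 100 * i, 100 * i + 50,
                superfamily=superfams[i % 4])
        for i in range(N)
    ]
    folds = []
    for _ in range(200):
        chosen = rng.choice(N, size=n, replace=False)
        events = [
            EventCall(
                gene_id=f"g{j}",
                te_id=f"te{i}",
                event=EventType.IR,
                subtype=EventSubtype.NONE,
                iso_with=f"g{j}.1",
                iso_without=f"g{j}.2",
                region=GenomicInterval("chr1", 0, 10, "+"),
                overlap_bp=5,
            )
            for j, i in enumerate(chosen)
        ]
        for r in superfamily_enrichment(tes, events, "IR"):
            folds.append(r.fold_enrichment)
    assert np.mean(folds) == pytest.approx(1.0, abs=0.03)


# ---------------------------------------------------------------------------
# splice-site windows


def _genome_with_intron(strand):
    seq = list("A" * 400)
    # intron [100, 200): canonical dinucleotides by strand
    if strand == "+":
        seq[100:102] = "GT"
        seq[198:200] = "AG"
    else:
        seq[100:102] = "CT"
        seq[198:200] = "AC"
    return GenomeSequence({"chr1": "".join(seq)})


@pytest.mark.parametrize("strand", ["+", "-"])
def test_ir_splice_windows_read_gt_ag(strand):
    a = make_tx("a", [(0, 100), (200, 300)], strand=strand)
    b = make_tx("b", [(0, 300)], strand=strand)
    gene = make_gene([a, b])
    te = make_te("te1", 90, 210)
    cfg = EventConfig()
    chim = detect_te_g_transcripts([gene], [te], cfg)
    events = call_ate_g_isoforms(chim, [gene], [te], cfg)
    windows = extract_ir_splice_sites(events, [gene], [te], _genome_with_intron(strand))
    assert {w.site_type for w in windows} == {"donor", "acceptor"}
    for w in windows:
        assert len(w.sequence) == 1 + 2 * SPLICE_WINDOW_FLANK
        if w.site_type == "donor":
            # intron positions +1/+2 sit just after the window centre
            assert w.sequence[4:6] == "GT"
        else:
            assert w.sequence[3:5] == "AG"


def test_donor_window_coordinates():
    a = make_tx("a", [(0, 100), (200, 300)])
    b = make_tx("b", [(0, 300)])
    gene = make_gene([a, b])
    te = make_te("te1", 90, 210)
    chim = detect_te_g_transcripts([gene], [te], EventConfig())
    events = call_ate_g_isoforms(chim, [gene], [te], EventConfig())
    windows = extract_ir_splice_sites(events, [gene], [te], _genome_with_intron("+"))
    donor = next(w for w in windows if w.site_type == "donor")
    assert (donor.window.start, donor.window.end) == (96, 105)


def test_windows_deduplicated_across_isoform_pairs():
    a = make_tx("a", [(0, 100), (200, 300)])
    b = make_tx("b", [(0, 300)])
    c = make_tx("c", [(0, 300), (320, 380)])
    gene = make_gene([a, b, c])
    te = make_te("te1", 90, 210)
    region = GenomicInterval("chr1", 100, 200, "+")
    # the same retained intron reported through two different isoform pairs
    events = [
        EventCall(gene.gene_id, te.te_id, EventType.IR, EventSubtype.NONE,
                  "b", "a", region, 40),
        EventCall(gene.gene_id, te.te_id, EventType.IR, EventSubtype.NONE,
                  "c", "a", region, 40),
    ]
    windows = extract_ir_splice_sites(events, [gene], [te], _genome_with_intron("+"))
    keys = [(w.site_type, w.site_position.start) for w in windows]
    assert len(keys) == len(set(keys)) == 2


def test_window_requires_te_overlap():
    a = make_tx("a", [(0, 100), (200, 300)])
    b = make_tx("b", [(0, 300)])
    gene = make_gene([a, b])
    te = make_te("te1", 130, 170)  # interior of the intron only
    chim = detect_te_g_transcripts([gene], [te], EventConfig())
    events = call_ate_g_isoforms(chim, [gene], [te], EventConfig())
    windows = extract_ir_splice_sites(events, [gene], [te], _genome_with_intron("+"))
    assert windows == []


def _uniform_windows(seqs, site_type="donor"):
    out = []
    for i, s in enumerate(seqs):
        pos = 100 + 20 * i
        out.append(
            SpliceSiteWindow(
                site_type,
                GenomicInterval("chr1", pos, pos + 1, "+"),
                GenomicInterval("chr1", pos - 4, pos + 5, "+"),
                s,
                te_id="te1",
            )
        )
    return out


def test_position_matrix_identical_windows():
    windows = _uniform_windows(["AAAAGTAAA"] * 10)
    df = position_nucleotide_enrichment(windows)
    g_plus1 = df[(df.position == 1) & (df.base == "G")].iloc[0]
    assert g_plus1["frequency"] == pytest.approx(1.0)
    assert g_plus1["count"] == 10
    a_plus1 = df[(df.position == 1) & (df.base == "A")].iloc[0]
    assert a_plus1["count"] == 0


def test_subset_equal_to_full_set_is_trivial():
    windows = _uniform_windows(["ACGTGTACG", "TTGAGTCCA", "ACGAGTTTT"])
    df = position_nucleotide_enrichment(windows, subset=windows)
    # drawing everything: p_over = 1 wherever the base occurs at all
    occupied = df[df["count"] > 0]
    assert np.allclose(occupied["p_over"], 1.0)


def test_pwm_recovery_from_generated_windows():
    """Base frequencies drawn from a fixed profile are recovered at n=1000."""
    rng = np.random.default_rng(3)
    probs = {"A": 0.1, "C": 0.2, "G": 0.6, "T": 0.1}
    bases, p = zip(*probs.items())
    seqs = [
        "".join(rng.choice(bases, p=p) for _ in range(9)) for _ in range(1000)
    ]
    df = position_nucleotide_enrichment(_uniform_windows(seqs))
    for base, prob in probs.items():
        freqs = df[df.base == base]["frequency"]
        # binomial sampling error at n = 1000: 3 sd ~ 0.047
        assert np.allclose(freqs, prob, atol=3 * np.sqrt(prob * (1 - prob) / 1000))


def test_window_fasta_shape():
    windows = _uniform_windows(["AAAAGTAAA"] * 2)
    text = window_fasta(windows)
    assert text.count(">") == 2
    assert "AAAAGTAAA" in text
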