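"""TE-superfamily enrichment and splice-site motif windows.

Enrichment of a superfamily within an event category is assessed against
the hypergeometric distribution: drawing the category's TEs from the
classified TE population, the expected superfamily count is K*n/N and the
over/under p-values are upper/lower tails of Hypergeom(N, K, n).  Raw
p-values are Benjamini-Hochberg corrected across superfamilies within each
category.

For intron-retention events, the retained intron's donor and acceptor
splice sites are extracted with a window of 4 nt on either side of the
boundary base (9 nt total), sequences oriented 5'->3' on the transcript
strand, so canonical introns read GT at donor positions +1/+2 and AG at
acceptor positions -2/-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotations import GenomeSequence
from .model import (
    AS_EVENTS,
    ATP_EVENTS,
    EventCall,
    EventType,
    GeneModel,
    GenomicInterval,
    TERecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "SpliceSiteWindow",
    "hypergeometric_tails",
    "superfamily_enrichment",
    "enrichment_table",
    "extract_ir_splice_sites",
    "position_nucleotide_enrichment",
    "window_fasta",
]

#: Window flank around the splice-site base, in nt.
SPLICE_WINDOW_FLANK = 4

_CATEGORY_GROUPS = {
    "AS": AS_EVENTS,
    "ATP": ATP_EVENTS,
    "ALL": AS_EVENTS | ATP_EVENTS,
}


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one superfamily in one event category."""

    superfamily: str
    category: str
    N_total: int
    K_superfamily: int
    n_category: int
    k_observed: int
    expected: float
    fold_enrichment: float
    fold_printed: float
    p_over: float
    p_under: float
    q_over: float = float("nan")
    q_under: float = float("nan")


def hypergeometric_tails(N, K, n, k):
    """Upper and lower tails (P(X >= k), P(X <= k)) of Hypergeom(N, K, n).

    Accepts scalars or equal-length arrays; returns a pair of arrays/floats.
    """
    p_over = hypergeom.sf(np.asarray(k) - 1, N, K, n)
    p_under = hypergeom.cdf(k, N, K, n)
    return np.minimum(p_over, 1.0), np.minimum(p_under, 1.0)


def _category_events(category) -> set[EventType]:
    if isinstance(category, EventType):
        return {category}
    cat = str(category).upper()
    if cat in _CATEGORY_GROUPS:
        return set(_CATEGORY_GROUPS[cat])
    try:
        return {EventType(cat)}
    except ValueError:
        raise ValueError(f"unknown event category {category!r}")


def superfamily_enrichment(
    tes: Sequence[TERecord],
    events: Sequence[EventCall],
    category,
) -> list[EnrichmentResult]:
    """Per-superfamily enrichment of TEs in one event category.

    ``category`` is an :class:`EventType`, its name, or one of the groups
    "AS" (IR/ES/A5SS/A3SS), "ATP" (ATSS/ATTS), "ALL".  The population N is
    the set of TEs surviving gene-like removal; k counts distinct TEs of the
    superfamily appearing in the category's events.  An empty category
    returns an empty list.
    """
    wanted = _category_events(category)
    cat_name = category.value if isinstance(category, EventType) else str(category)

    population = [te for te in tes if not te.removed_gene_like]
    N = len(population)
    sf_of = {te.te_id: te.superfamily for te in population}
    in_cat = {ev.te_id for ev in events if ev.event in wanted and ev.te_id in sf_of}
    n = len(in_cat)
    if n == 0:
        return []

    superfamilies = sorted({te.superfamily for te in population})
    K_by_sf: dict[str, int] = {sf: 0 for sf in superfamilies}
    for te in population:
        K_by_sf[te.superfamily] += 1
    k_by_sf: dict[str, int] = {sf: 0 for sf in superfamilies}
    for te_id in in_cat:
        k_by_sf[sf_of[te_id]] += 1

    results: list[EnrichmentResult] = []
    for sf in superfamilies:
        K, k = K_by_sf[sf], k_by_sf[sf]
        expected = K * n / N
        fold = k / expected if expected > 0 else float("nan")
        fold_printed = expected / k if k > 0 else float("nan")
        p_over, p_under = hypergeometric_tails(N, K, n, k)
        p_over, p_under = float(p_over), float(p_under)
        results.append(
            EnrichmentResult(
                superfamily=sf,
                category=cat_name,
                N_total=N,
                K_superfamily=K,
                n_category=n,
                k_observed=k,
                expected=expected,
                fold_enrichment=fold,
                fold_printed=fold_printed,
                p_over=min(p_over, 1.0),
                p_under=min(p_under, 1.0),
            )
        )
    if len(results) > 0:
        q_over = multipletests([r.p_over for r in results], method="fdr_bh")[1]
        q_under = multipletests([r.p_under for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                **{
                    **r.__dict__,
                    "q_over": float(qo),
                    "q_under": float(qu),
                }
            )
            for r, qo, qu in zip(results, q_over, q_under)
        ]
    return results


def enrichment_table(
    tes: Sequence[TERecord],
    events: Sequence[EventCall],
    categories: Sequence = ("IR", "ES", "A5SS", "A3SS", "ATSS", "ATTS", "AS", "ATP"),
) -> pd.DataFrame:
    """Enrichment results for several categories as one tidy DataFrame."""
    rows = []
    for cat in categories:
        for r in superfamily_enrichment(tes, events, cat):
            rows.append(r.__dict__)
    cols = [
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
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# splice-site windows for intron retention


@dataclass(frozen=True)
class SpliceSiteWindow:
    """A +/-4 nt window around a donor or acceptor splice-site base."""

    site_type: str  # "donor" | "acceptor"
    site_position: GenomicInterval  # 1 bp at the boundary base
    window: GenomicInterval
    sequence: str  # 5'->3' on the transcript strand
    te_id: str

    def __post_init__(self) -> None:
        if self.window.length != self.site_position.length + 2 * SPLICE_WINDOW_FLANK:
            raise ValueError("window must be the site plus 4 nt on each side")


def _ir_intron_sites(region: GenomicInterval, strand: str) -> list[tuple[str, int]]:
    """(site_type, genomic position of boundary base) for a retained intron.

    The donor base is the first intron base 5'->3'; the acceptor base is the
    last.  On the - strand these swap genomic ends.
    """
    first, last = region.start, region.end - 1
    if strand == "+":
        return [("donor", first), ("acceptor", last)]
    return [("donor", last), ("acceptor", first)]


def extract_ir_splice_sites(
    events: Sequence[EventCall],
    genes: Sequence[GeneModel],
    tes: Sequence[TERecord],
    genome: GenomeSequence,
) -> list[SpliceSiteWindow]:
    """Splice-site windows of retained introns in TE-IR events.

    The donor and acceptor are taken from the retained intron (the region of
    the IR event, i.e. the intron of the spliced isoform).  Sites are
    deduplicated on (chrom, position, strand, type); only windows that
    overlap a TE involved in an IR event are kept.  Sequences are extracted
    5'->3' on the transcript strand.
    """
    strand_of = {
        t.transcript_id: t.strand for g in genes for t in g.transcripts
    }
    ir_events = [ev for ev in events if ev.event is EventType.IR]
    ir_te_ids = {ev.te_id for ev in ir_events}
    ir_tes = [te for te in tes if te.te_id in ir_te_ids]

    windows: list[SpliceSiteWindow] = []
    seen: set[tuple] = set()
    for ev in ir_events:
        strand = strand_of.get(ev.iso_without) or ev.region.strand
        if strand not in ("+", "-"):
            logger.warning("IR event at %s lacks strand; skipped", ev.region)
            continue
        for site_type, pos in _ir_intron_sites(ev.region, strand):
            key = (ev.region.chrom, pos, strand, site_type)
            if key in seen:
                continue
            seen.add(key)
            win = GenomicInterval(
                ev.region.chrom,
                pos - SPLICE_WINDOW_FLANK,
                pos + 1 + SPLICE_WINDOW_FLANK,
                strand,
            )
            overlapping = [
                te for te in ir_tes if te.interval.overlap_bp(win) >= 1
            ]
            if not overlapping:
                continue
            seq = genome.fetch(win.chrom, win.start, win.end, strand)
            site = GenomicInterval(win.chrom, pos, pos + 1, strand)
            # attribute the window to the closest overlapping IR TE
            te_id = sorted(
                overlapping, key=lambda te: (-te.interval.overlap_bp(win), te.te_id)
            )[0].te_id
            windows.append(SpliceSiteWindow(site_type, site, win, seq, te_id))
    return windows


def position_nucleotide_enrichment(
    windows: Sequence[SpliceSiteWindow],
    subset: Optional[Sequence[SpliceSiteWindow]] = None,
    background: Optional[dict[str, float]] = None,
    subset_label: str = "all",
) -> pd.DataFrame:
    """Per-position base counts, frequencies and enrichment of windows.

    Positions follow splice-site nomenclature (no position 0): donor windows
    run exon -4..-1 then intron +1..+5, so a canonical donor reads GT at
    +1/+2; acceptor windows run intron -5..-1 then exon +1..+4, so a
    canonical acceptor reads AG at -2/-1.  ``fold`` compares the subset's
    base frequency with ``background`` (uniform 0.25 when None); ``p_over``
    is the hypergeometric upper tail of the subset's base count drawn from
    the full window set at that position.  N bases are excluded from
    counting (logged).
    """
    if not windows:
        raise ValueError("no splice-site windows supplied")
    if subset is None:
        subset = windows
    if background is None:
        background = {b: 0.25 for b in "ACGT"}
    width = len(windows[0].sequence)

    def offsets_for(site_type: str) -> list[int]:
        # the window centre base is intron +1 (donor) or intron -1 (acceptor)
        if site_type == "donor":
            raw = range(-SPLICE_WINDOW_FLANK, width - SPLICE_WINDOW_FLANK)
        else:
            raw = range(-SPLICE_WINDOW_FLANK - 1, width - SPLICE_WINDOW_FLANK - 1)
        return [p if p < 0 else p + 1 for p in raw]

    def counts_of(wins, offsets):
        counts = {(pos, b): 0 for pos in offsets for b in "ACGT"}
        n_skipped = 0
        for w in wins:
            for pos, base in zip(offsets, w.sequence):
                if base in "ACGT":
                    counts[(pos, base)] += 1
                else:
                    n_skipped += 1
        if n_skipped:
            logger.warning("%d non-ACGT window bases excluded", n_skipped)
        return counts

    rows = []
    for site_type in sorted({w.site_type for w in subset}):
        offsets = offsets_for(site_type)
        st_all = [w for w in windows if w.site_type == site_type]
        st_sub = [w for w in subset if w.site_type == site_type]
        ac = counts_of(st_all, offsets)
        sc = counts_of(st_sub, offsets)
        for pos in offsets:
            N = sum(ac[(pos, b)] for b in "ACGT")
            n = sum(sc[(pos, b)] for b in "ACGT")
            for base in "ACGT":
                K = ac[(pos, base)]
                k = sc[(pos, base)]
                freq = k / n if n else float("nan")
                fold = freq / background[base] if background[base] > 0 else float("nan")
                p_over = float(hypergeom.sf(k - 1, N, K, n)) if n else float("nan")
                rows.append(
                    {
                        "site_type": site_type,
                        "subset": subset_label,
                        "position": pos,
                        "base": base,
                        "count": k,
                        "frequency": freq,
                        "background_frequency": background[base],
                        "fold": fold,
                        "p_over": min(p_over, 1.0) if p_over == p_over else p_over,
                    }
                )
    return pd.DataFrame(rows)


def window_fasta(windows: Sequence[SpliceSiteWindow]) -> str:
    """FASTA text of window sequences (for external logo tools)."""
    parts = []
    for w in sorted(windows, key=lambda w: (w.site_type, w.window.chrom, w.window.start)):
        name = f"{w.site_type}|{w.window.chrom}:{w.window.start}-{w.window.end}({w.window.strand})|{w.te_id}"
        parts.append(f">{name}\n{w.sequence}")
    return "\n".join(parts) + ("\n" if parts else "")
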