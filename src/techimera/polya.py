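"""Poly(A)-site windows and their intersection with ATTS-associated TEs.

Poly(A) sites come in as 1-bp anchors (the 3' end of a polyadenylated read,
or a database site).  Each anchor is expanded to a +/-10 bp window (the
uncertainty of the soft-clipped 3' terminus); windows are intersected with
the TEs driving alternative-termination (ATTS) events to ask how often an
alternative 3' end falls inside TE sequence.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import EventCall, EventType, GenomicInterval, TERecord

logger = logging.getLogger(__name__)

__all__ = [
    "PolyASite",
    "read_polya_bed",
    "build_polya_windows",
    "atts_tes",
    "tes_with_polya",
]


@dataclass(frozen=True)
class PolyASite:
    """A poly(A)-site anchor with its +/-flank search window."""

    site: GenomicInterval  # 1 bp anchor
    window: GenomicInterval
    source: str = "read_3prime"  # or "database"
    support: float = 1.0


def read_polya_bed(
    path: str | os.PathLike, source: str = "read_3prime"
) -> list[GenomicInterval]:
    """Read 1-bp poly(A) anchors from a BED file (start coordinate used)."""
    anchors: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start = fields[0], int(fields[1])
            strand = fields[5] if len(fields) >= 6 else "."
            anchors.append(GenomicInterval(chrom, start, start + 1, strand))
    return anchors


def build_polya_windows(
    anchors: Sequence[GenomicInterval],
    flank: int = 10,
    source: str = "read_3prime",
) -> list[PolyASite]:
    """Expand each 1-bp anchor to an anchor +/- ``flank`` window.

    Overlapping windows are deliberately not merged: each anchor is one
    site.  Windows running off the left contig end are clamped at 0 with a
    warning.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    sites: list[PolyASite] = []
    n_clamped = 0
    for a in anchors:
        anchor_pos = a.start
        lo = anchor_pos - flank
        if lo < 0:
            n_clamped += 1
            lo = 0
        win = GenomicInterval(a.chrom, lo, anchor_pos + flank + 1, a.strand)
        sites.append(PolyASite(site=a, window=win, source=source))
    if n_clamped:
        logger.warning("%d poly(A) windows clamped at contig start", n_clamped)
    return sites


def atts_tes(events: Sequence[EventCall], tes: Sequence[TERecord]) -> list[TERecord]:
    """TEs appearing in ATTS events (each TE once)."""
    wanted = {ev.te_id for ev in events if ev.event is EventType.ATTS}
    return [te for te in tes if te.te_id in wanted]


def tes_with_polya(
    atts_te_records: Sequence[TERecord],
    sites: Sequence[PolyASite],
    stranded: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Intersect ATTS-TE intervals with poly(A) windows.

    Returns a per-TE table (has_site, window counts, per-source breakdown)
    and a summary with the fraction of ATTS TEs containing at least one
    site.  With ``stranded`` the window strand must match the TE strand.
    """
    rows = []
    for te in atts_te_records:
        n_total = 0
        per_source: dict[str, int] = {"read_3prime": 0, "database": 0}
        for s in sites:
            if stranded and s.window.strand != te.interval.strand:
                continue
            if te.interval.overlap_bp(s.window) >= 1:
                n_total += 1
                per_source[s.source] = per_source.get(s.source, 0) + 1
        rows.append(
            {
                "te_id": te.te_id,
                "chrom": te.chrom,
                "start": te.interval.start,
                "end": te.interval.end,
                "has_site": n_total > 0,
                "n_windows": n_total,
                "n_read_3prime": per_source.get("read_3prime", 0),
                "n_database": per_source.get("database", 0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "te_id",
            "chrom",
            "start",
            "end",
            "has_site",
            "n_windows",
            "n_read_3prime",
            "n_database",
        ],
    )
    n_tes = len(table)
    n_with = int(table["has_site"].sum()) if n_tes else 0
    summary = {
        "n_atts_tes": n_tes,
        "n_tes_with_site": n_with,
        "fraction_tes_with_site": n_with / n_tes if n_tes else 0.0,
    }
    return table, summary
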