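"""Cytosine methylation calling and TE-level summaries.

Input is a per-cytosine count table (the de facto "CX"-style report:
chrom, pos, strand, context, count_meth, count_unmeth).  Calling follows the
negative-control recipe: an unmethylated control contig (typically the
mitochondrial genome) yields a per-context conversion/sequencing error rate;
each covered site is then tested with a one-sided binomial test against
that error rate, Benjamini-Hochberg corrected per context, and sites with
q >= threshold are treated as unmethylated.  Methylation levels are the
coverage-weighted ratio mC/(mC + unmC); TE-level percentages require at
least five covered cytosines.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .model import TERecord

logger = logging.getLogger(__name__)

__all__ = [
    "TEMethylationSummary",
    "CONTEXTS",
    "read_cytosine_table",
    "write_cytosine_table",
    "estimate_error_rate",
    "call_sites",
    "te_methylation",
    "methylation_table",
    "to_bedgraph",
]

CONTEXTS = ("CG", "CHG", "CHH")

_COLUMNS = ["chrom", "pos", "strand", "context", "count_meth", "count_unmeth"]


@dataclass(frozen=True)
class TEMethylationSummary:
    """Percent methylation of one TE in one context (>= 5 covered sites)."""

    te_id: str
    context: str
    covered_cytosines: int
    percent_methylation: float
    delta_vs_control: Optional[float] = None


def read_cytosine_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-cytosine TSV (chrom, pos, strand, context, counts)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["context"].unique()) - set(CONTEXTS)
    if bad:
        raise ValueError(f"{path}: invalid methylation contexts {sorted(bad)}")
    return df


def write_cytosine_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.reindex(columns=[c for c in df.columns]).to_csv(path, sep="\t", index=False)


def estimate_error_rate(
    records: pd.DataFrame, control_contig: str
) -> dict[str, float]:
    """Per-context error rate from an unmethylated control contig.

    error = sum(count_meth) / sum(coverage) over the control cytosines of
    each context.  Raises when the control contig has no covered cytosines.
    """
    ctrl = records[records["chrom"] == control_contig]
    cov = ctrl["count_meth"] + ctrl["count_unmeth"]
    if len(ctrl) == 0 or int(cov.sum()) == 0:
        raise ValueError(
            f"control contig {control_contig!r} has no covered cytosines"
        )
    rates: dict[str, float] = {}
    for context in CONTEXTS:
        sub = ctrl[ctrl["context"] == context]
        total = int((sub["count_meth"] + sub["count_unmeth"]).sum())
        meth = int(sub["count_meth"].sum())
        rates[context] = meth / total if total else 0.0
    return rates


def call_sites(
    records: pd.DataFrame,
    error_rate: dict[str, float] | float,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Binomial methylation calls per site with per-context BH correction.

    For each covered site, p = P(X >= count_meth) for X ~ Binom(coverage,
    error_rate[context]); q-values are Benjamini-Hochberg within each
    context; ``called_methylated`` = (q < q_threshold).  Sites without
    coverage get no call (False).  Returns a copy with columns ``p_value``,
    ``q_value`` and ``called_methylated``.
    """
    if isinstance(error_rate, float):
        error_rate = {c: error_rate for c in CONTEXTS}
    for c, e in error_rate.items():
        if not (0 <= e < 1):
            raise ValueError(f"error rate for {c} must be in [0, 1)")
    out = records.copy()
    cov = (out["count_meth"] + out["count_unmeth"]).to_numpy()
    meth = out["count_meth"].to_numpy()
    p = np.ones(len(out))
    for context in CONTEXTS:
        mask = (out["context"] == context).to_numpy() & (cov > 0)
        if not mask.any():
            continue
        # one-sided upper tail: P(X >= meth) = sf(meth - 1)
        p[mask] = binom.sf(meth[mask] - 1, cov[mask], error_rate[context])
    out["p_value"] = p
    q = np.ones(len(out))
    for context in CONTEXTS:
        mask = (out["context"] == context).to_numpy() & (cov > 0)
        if mask.any():
            q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    out["q_value"] = q
    out["called_methylated"] = (out["q_value"] < q_threshold) & (cov > 0)
    return out


def _te_context_stats(
    records: pd.DataFrame,
    tes: Sequence[TERecord],
    min_covered: int,
    per_site_mean: bool,
    apply_calls: bool,
) -> dict[tuple[str, str], tuple[int, float]]:
    """(te_id, context) -> (covered sites, percent methylation)."""
    df = records
    cov = df["count_meth"] + df["count_unmeth"]
    df = df[cov > 0]
    if apply_calls and "called_methylated" in df.columns:
        # sites not called methylated contribute zero methylated reads
        meth = df["count_meth"].where(df["called_methylated"], 0)
        df = df.assign(
            count_meth=meth,
            count_unmeth=(df["count_meth"] + df["count_unmeth"]) - meth,
        )
    stats: dict[tuple[str, str], tuple[int, float]] = {}
    by_chrom = {chrom: sub for chrom, sub in df.groupby("chrom")}
    for te in tes:
        sub = by_chrom.get(te.chrom)
        if sub is None:
            continue
        inside = sub[(sub["pos"] >= te.interval.start) & (sub["pos"] < te.interval.end)]
        for context in CONTEXTS:
            csub = inside[inside["context"] == context]
            n_sites = len(csub)
            if n_sites < min_covered:
                continue
            if per_site_mean:
                ratios = csub["count_meth"] / (
                    csub["count_meth"] + csub["count_unmeth"]
                )
                pct = 100.0 * float(ratios.mean())
            else:
                total = int((csub["count_meth"] + csub["count_unmeth"]).sum())
                pct = 100.0 * float(csub["count_meth"].sum()) / total
            stats[(te.te_id, context)] = (n_sites, pct)
    return stats


def te_methylation(
    records: pd.DataFrame,
    tes: Sequence[TERecord],
    control_records: Optional[pd.DataFrame] = None,
    min_covered: int = 5,
    per_site_mean: bool = False,
    apply_calls: bool = True,
) -> list[TEMethylationSummary]:
    """Percent methylation per TE and context.

    The default aggregation is coverage-weighted pooling within the TE
    interval, 100 * sum(mC) / sum(mC + unmC); ``per_site_mean`` averages
    per-site ratios instead.  TEs with fewer than ``min_covered`` covered
    cytosines in a context are suppressed for that context.  When a second
    sample is given (e.g. a hypomethylation mutant vs wild type),
    ``delta_vs_control`` = percent - control percent wherever both samples
    pass the coverage floor.
    """
    stats = _te_context_stats(records, tes, min_covered, per_site_mean, apply_calls)
    ctrl_stats = (
        _te_context_stats(control_records, tes, min_covered, per_site_mean, apply_calls)
        if control_records is not None
        else {}
    )
    out: list[TEMethylationSummary] = []
    for te in tes:
        for context in CONTEXTS:
            key = (te.te_id, context)
            if key not in stats:
                continue
            n_sites, pct = stats[key]
            delta = None
            if key in ctrl_stats:
                delta = pct - ctrl_stats[key][1]
            out.append(
                TEMethylationSummary(
                    te_id=te.te_id,
                    context=context,
                    covered_cytosines=n_sites,
                    percent_methylation=pct,
                    delta_vs_control=delta,
                )
            )
    return out


def methylation_table(summaries: Sequence[TEMethylationSummary]) -> pd.DataFrame:
    rows = [
        {
            "te_id": s.te_id,
            "context": s.context,
            "covered_cytosines": s.covered_cytosines,
            "percent_methylation": s.percent_methylation,
            "delta_vs_control": s.delta_vs_control,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "te_id",
            "context",
            "covered_cytosines",
            "percent_methylation",
            "delta_vs_control",
        ],
    )


def to_bedgraph(records: pd.DataFrame, context: str) -> str:
    """bedGraph text of per-site methylation levels for one context."""
    sub = records[records["context"] == context]
    cov = sub["count_meth"] + sub["count_unmeth"]
    sub = sub[cov > 0]
    lines = [f'track type=bedGraph name="methylation_{context}"']
    sub = sub.sort_values(["chrom", "pos"], kind="mergesort")
    for _, row in sub.iterrows():
        level = row["count_meth"] / (row["count_meth"] + row["count_unmeth"])
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{int(row['pos']) + 1}\t{level:.4f}"
        )
    return "\n".join(lines) + "\n"
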