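"""Per-context methylation summaries and binned genome profiles.

The headline statistic is the per-context methylation percentage

    pct(c) = 100 * ( sum of per-site fractions ) / ( number of called sites )

i.e. an *unweighted* mean of per-site modification fractions over the called
records of context *c* — it divides by the motif count, not by total reads, so
deep sites do not dominate. Sites are "called" once they pass the per-context
coverage cutoff (30x for CpG, Dcm and Dam by default; the de novo CHH channel
has no read-depth floor beyond 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default coverage cutoffs per context (reads). Boundary inclusive: a site
#: at exactly the cutoff is kept.
DEFAULT_MIN_COVERAGE = {"CpG": 30, "Dcm": 30, "Dam": 30, "CHG": 1, "CHH": 1}


@dataclass(frozen=True)
class ContextSummary:
    context: str
    n_motifs: int
    methylation_pct: float
    mean_coverage: float
    median_coverage: float
    median: float
    q1: float
    q3: float


class NoCalledMotifsError(ValueError):
    """Raised when a summary is requested for a context with zero records."""


def filter_by_coverage(records: pd.DataFrame, min_cov_by_context: dict | None = None) -> pd.DataFrame:
    """Drop records below their context's coverage cutoff (inclusive keep)."""
    cutoffs = dict(DEFAULT_MIN_COVERAGE)
    if min_cov_by_context:
        cutoffs.update(min_cov_by_context)
    if any(v < 0 for v in cutoffs.values()):
        raise ValueError("coverage cutoffs must be non-negative")
    thresh = records["context"].map(cutoffs).fillna(1)
    return records[records["coverage"] >= thresh].reset_index(drop=True)


def context_methylation_pct(records: pd.DataFrame, context: str) -> ContextSummary:
    """Summarise one context: methylation %, coverage, fraction quartiles.

    ``records`` should already be coverage-filtered. Raises
    :class:`NoCalledMotifsError` for a context with no records — an absent
    context is not 0% methylated.
    """
    sub = records[records["context"] == context]
    if sub.empty:
        raise NoCalledMotifsError(f"no called motifs for context {context!r}")
    frac = sub["fraction"].to_numpy(float)
    q1, med, q3 = np.percentile(frac, [25, 50, 75])
    return ContextSummary(
        context=context,
        n_motifs=len(sub),
        methylation_pct=100.0 * float(frac.mean()),
        mean_coverage=float(sub["coverage"].mean()),
        median_coverage=float(sub["coverage"].median()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def summarize_contexts(records: pd.DataFrame, split_chh_by_strand: bool = True) -> pd.DataFrame:
    """One summary row per context present, CHH optionally split by strand."""
    rows = []
    for ctx in sorted(records["context"].unique()):
        if ctx == "CHH" and split_chh_by_strand:
            for strand, tag in (("+", "CHH_fwd"), ("-", "CHH_rev")):
                sub = records[(records["context"] == "CHH") & (records["strand"] == strand)]
                if not sub.empty:
                    s = context_methylation_pct(sub, "CHH")
                    rows.append({**s.__dict__, "context": tag})
        else:
            rows.append(context_methylation_pct(records, ctx).__dict__)
    return pd.DataFrame(rows)


def bin_genome(
    records: pd.DataFrame,
    genome_length: int,
    width: int = 100_000,
    split_chh_by_strand: bool = True,
) -> pd.DataFrame:
    """Mean methylation level per non-overlapping genomic bin.

    Bin *i* (1-based) covers [(i-1)*width + 1, min(i*width, L)]; the last bin
    may be partial. Per bin and context the value is 100x the unweighted mean
    fraction of called records located in the bin; bins with no records carry
    NaN (missing), which is distinct from 0% — a depleted region reports 0,
    an uncovered one reports nothing. CHH is additionally split by strand.

    Returns a frame with one row per (bin, context) and columns
    ``bin, start, end, context, methylation_pct, n_sites``.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if len(records) and (records["position"] > genome_length).any():
        bad = records.loc[records["position"] > genome_length, "position"].iloc[0]
        raise ValueError(f"record position {bad} beyond genome length {genome_length}")

    n_bins = -(-genome_length // width)  # ceiling division
    rec = records.copy()
    rec["channel"] = rec["context"]
    if split_chh_by_strand:
        chh = rec["context"] == "CHH"
        rec.loc[chh, "channel"] = np.where(rec.loc[chh, "strand"] == "+", "CHH_fwd", "CHH_rev")
    rec["bin"] = (rec["position"] - 1) // width + 1

    grouped = rec.groupby(["bin", "channel"])["fraction"].agg(["mean", "size"])
    channels = sorted(rec["channel"].unique())
    rows = []
    for b in range(1, n_bins + 1):
        start = (b - 1) * width + 1
        end = min(b * width, genome_length)
        for ch in channels:
            if (b, ch) in grouped.index:
                mean, n = grouped.loc[(b, ch)]
                rows.append((b, start, end, ch, 100.0 * mean, int(n)))
            else:
                rows.append((b, start, end, ch, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["bin", "start", "end", "context", "methylation_pct", "n_sites"]
    )
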