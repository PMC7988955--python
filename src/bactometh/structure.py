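"""Strand-resolved gene distribution, GC content/skew tracks, and the
gene-strand-bias vs reverse-strand mCHH relationship.

Bacterial chromosomes often place genes preferentially on the leading strand;
per-Mb forward/reverse gene counts expose large-scale strand blocks, GC skew
(G-C)/(G+C) marks the replichore structure, and a rank correlation asks
whether reverse-strand gene density co-varies (negatively) with reverse-strand
asymmetric cytosine methylation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import GeneFeature, GenomeSequence

log = logging.getLogger(__name__)


def strand_gene_counts(
    genes: list[GeneFeature],
    genome_length: int,
    width: int = 1_000_000,
    by: str = "start",
) -> pd.DataFrame:
    """Forward/reverse gene counts per genomic bin, with a totals row.

    A gene belongs to the bin containing its start coordinate (or midpoint
    with ``by='midpoint'``); the last bin may be partial. Columns:
    start, end, forward, reverse, sum, difference (absolute).
    """
    if by not in ("start", "midpoint"):
        raise ValueError("by must be 'start' or 'midpoint'")
    n_bins = -(-genome_length // width)
    fwd = np.zeros(n_bins, dtype=np.int64)
    rev = np.zeros(n_bins, dtype=np.int64)
    for g in genes:
        anchor = g.start if by == "start" else (g.start + g.end) // 2
        if not 1 <= anchor <= genome_length:
            raise ValueError(f"gene {g.feature_id} anchor {anchor} outside [1, {genome_length}]")
        b = (anchor - 1) // width
        (fwd if g.strand == "+" else rev)[b] += 1
    rows = []
    for b in range(n_bins):
        start = b * width + 1
        end = min((b + 1) * width, genome_length)
        rows.append((start, end, fwd[b], rev[b], fwd[b] + rev[b], abs(int(fwd[b]) - int(rev[b]))))
    df = pd.DataFrame(rows, columns=["start", "end", "forward", "reverse", "sum", "difference"])
    totals = pd.DataFrame(
        [
            {
                "start": 1,
                "end": genome_length,
                "forward": int(fwd.sum()),
                "reverse": int(rev.sum()),
                "sum": int(fwd.sum() + rev.sum()),
                "difference": abs(int(fwd.sum()) - int(rev.sum())),
            }
        ],
        index=["total"],
    )
    return pd.concat([df, totals])


def gc_tracks(genome: GenomeSequence, window: int = 10_000, step: int | None = None) -> pd.DataFrame:
    """Sliding-window GC content and GC skew.

    GC content = (G+C)/(A+C+G+T); skew = (G-C)/(G+C), 0 for windows with no
    G or C (sign convention: G-rich positive). Windows wrap the origin on
    circular genomes; N bases are excluded from the denominators.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or window
    L = len(genome)
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    is_g = (seq == ord("G")).astype(np.int64)
    is_c = (seq == ord("C")).astype(np.int64)
    is_acgt = np.isin(seq, [ord(b) for b in "ACGT"]).astype(np.int64)
    cg_g = np.concatenate([[0], np.cumsum(is_g)])
    cg_c = np.concatenate([[0], np.cumsum(is_c)])
    cg_n = np.concatenate([[0], np.cumsum(is_acgt)])

    def _count(cum, a, b):  # 1-based inclusive, may wrap
        if b <= L:
            return cum[b] - cum[a - 1]
        return (cum[L] - cum[a - 1]) + cum[b - L]

    rows = []
    starts = range(1, L + 1, step) if genome.circular else range(1, L - window + 2, step)
    for s in starts:
        e = s + window - 1
        if not genome.circular and e > L:
            break
        g = _count(cg_g, s, e)
        c = _count(cg_c, s, e)
        n = _count(cg_n, s, e)
        content = (g + c) / n if n else np.nan
        skew = (g - c) / (g + c) if (g + c) else 0.0
        rows.append((s, min(e, L) if not genome.circular else e, g, c, content, skew))
    df = pd.DataFrame(rows, columns=["start", "end", "g", "c", "gc_content", "gc_skew"])
    return df


def strand_bias_methylation_correlation(
    strand_table: pd.DataFrame,
    bin_profile: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Spearman correlation between per-bin strand gene counts and mCHH.

    ``strand_table`` comes from :func:`strand_gene_counts` (totals row
    ignored); ``bin_profile`` from :func:`bactometh.stats.bin_genome` and is
    re-binned onto the strand table's grid by record-count-weighted mean.
    Reports rho for (reverse genes vs reverse-strand mCHH) and (forward genes
    vs forward-strand mCHH), each with a seeded permutation p-value; with
    fewer than 4 usable bins rho is reported as NaN (undefined).
    """
    bins = strand_table.loc[strand_table.index != "total"].reset_index(drop=True)
    out = {"n_bins": len(bins)}
    rng = np.random.default_rng(seed)
    for gene_col, channel, key in (
        ("reverse", "CHH_rev", "reverse"),
        ("forward", "CHH_fwd", "forward"),
    ):
        meth = _rebin(bin_profile, channel, bins)
        genes = bins[gene_col].to_numpy(float)
        ok = ~np.isnan(meth)
        res = {"rho": np.nan, "p_value": np.nan, "n": int(ok.sum())}
        if ok.sum() >= 4:
            x, y = genes[ok], meth[ok]
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                log.warning("constant input for %s correlation; rho undefined", key)
            else:
                rho = spearmanr(x, y).statistic
                count = 0
                for _ in range(n_permutations):
                    r = spearmanr(x, rng.permutation(y)).statistic
                    if abs(r) >= abs(rho):
                        count += 1
                res = {
                    "rho": float(rho),
                    "p_value": (1 + count) / (1 + n_permutations),
                    "n": int(ok.sum()),
                }
        else:
            log.warning("fewer than 4 bins for %s correlation; rho undefined", key)
        out[key] = res
    return out


def _rebin(bin_profile: pd.DataFrame, channel: str, bins: pd.DataFrame) -> np.ndarray:
    """Record-count-weighted mean methylation of ``channel`` per target bin."""
    sub = bin_profile[bin_profile["context"] == channel]
    out = np.full(len(bins), np.nan)
    for i, row in bins.iterrows():
        inside = sub[(sub["start"] >= row["start"]) & (sub["start"] <= row["end"])]
        inside = inside[inside["n_sites"] > 0]
        if len(inside):
            w = inside["n_sites"].to_numpy(float)
            out[i] = float(np.average(inside["methylation_pct"], weights=w))
    return out
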