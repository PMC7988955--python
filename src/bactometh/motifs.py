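"""De novo discovery of enriched methylated-base motifs.

Given per-base modification calls, highly modified sites of one base (A or C)
form a foreground set; the sequence context of each site (a +/-``flank``
window read 5'->3' on the site's own strand) is decomposed into every k-mer
that covers the modified base, and each (k-mer, modified-base offset) pair is
tested for enrichment of the foreground over the genomic background of *all*
sites of that base. Because the background is all same-base positions on both
strands, base-composition bias cancels exactly. Enrichment is a pseudocounted
log2 rate ratio; significance is a one-sided binomial test at the background
rate with Bonferroni correction. The consensus is printed with the modified
base bracketed, e.g. ``G(A)ACT`` for adenine methylated in the GAACT motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenomeSequence, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"


@dataclass(frozen=True)
class EnrichedMotif:
    consensus: str  # e.g. "G(A)ACT"
    kmer: str
    offset: int  # 0-based index of the modified base within the k-mer
    foreground: int
    background: int
    log2_enrichment: float
    p_value: float
    p_bonferroni: float
    fraction_median: float
    fraction_q1: float
    fraction_q3: float


def select_modified_sites(
    records: pd.DataFrame, base: str, min_fraction: float = 0.5, min_cov: int = 10
) -> pd.DataFrame:
    """Foreground site selection: one base, well covered, highly modified."""
    sel = (
        (records["base"] == base)
        & (records["coverage"] >= min_cov)
        & (records["fraction"] >= min_fraction)
    )
    return records.loc[sel, ["position", "strand", "fraction"]].reset_index(drop=True)


def enrich_kmers(
    genome: GenomeSequence,
    sites: pd.DataFrame,
    base: str,
    k: int = 5,
    flank: int = 4,
    min_sites: int = 20,
    alpha: float = 0.01,
) -> list[EnrichedMotif]:
    """Rank (k-mer, offset) motifs enriched among modified sites.

    Returns motifs passing the Bonferroni-corrected binomial threshold,
    highest enrichment first, with overlapping/nested variants of the same
    context collapsed onto the best-scoring representative.
    """
    if len(sites) < min_sites:
        raise ValueError(f"need >= {min_sites} foreground sites, got {len(sites)}")
    if not 1 <= k <= 2 * flank + 1:
        raise ValueError("k must fit inside the extracted window")

    fg_counts, n_fg = _site_kmer_counts(
        genome, sites["position"].to_numpy(np.int64), sites["strand"].to_numpy(), k, flank
    )
    bg_counts, n_bg = _background_kmer_counts(genome, base, k, flank)

    n_tests = max(len(bg_counts), 1)
    fracs = sites["fraction"].to_numpy(float)
    q1, med, q3 = np.percentile(fracs, [25, 50, 75])

    motifs = []
    for key, f in fg_counts.items():
        b = bg_counts.get(key, 0)
        kmer, off = key
        enr = np.log2(((f + 1) / (n_fg + 2)) / ((b + 1) / (n_bg + 2)))
        p = float(sps.binom.sf(f - 1, n_fg, b / n_bg)) if b else float(sps.binom.sf(f - 1, n_fg, 1 / n_bg))
        p_adj = min(p * n_tests, 1.0)
        if p_adj < alpha and enr > 0:
            cons = f"{kmer[:off]}({kmer[off]}){kmer[off + 1:]}"
            motifs.append(
                EnrichedMotif(cons, kmer, off, f, b, float(enr), p, p_adj,
                              float(med), float(q1), float(q3))
            )
    motifs.sort(key=lambda m: (-m.log2_enrichment, m.p_value))
    return _collapse_overlapping(motifs)


def motif_table(motifs: list[EnrichedMotif]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in motifs])


def _collapse_overlapping(motifs: list[EnrichedMotif]) -> list[EnrichedMotif]:
    """Keep the best-scoring representative of each aligned motif family.

    Two motifs are views of one context when, aligned at the modified base,
    all overlapping characters agree.
    """
    kept: list[EnrichedMotif] = []
    for m in motifs:
        if not any(_same_context(m, other) for other in kept):
            kept.append(m)
    return kept


def _same_context(a: EnrichedMotif, b: EnrichedMotif) -> bool:
    shift = b.offset - a.offset  # align modified bases
    lo = max(0, -shift)
    hi = min(len(a.kmer), len(b.kmer) - shift)
    if hi - lo < 2:  # only the modified base itself overlaps: unrelated
        return False
    return all(a.kmer[i] == b.kmer[i + shift] for i in range(lo, hi))


def _window_matrix(genome: GenomeSequence, positions: np.ndarray, strands: np.ndarray, flank: int) -> np.ndarray:
    """(n, 2*flank+1) base-code matrix of each site's own-strand window."""
    L = len(genome)
    fwd = np.array([_CODE[c] for c in genome.sequence], dtype=np.int8)
    offs = np.arange(-flank, flank + 1)
    idx = (positions[:, None] - 1 + offs[None, :])
    if genome.circular:
        idx %= L
        win = fwd[idx]
    else:
        valid = (idx >= 0) & (idx < L)
        win = np.where(valid, fwd[np.clip(idx, 0, L - 1)], 4)
    rev = strands == "-"
    # reverse-strand windows: reverse order and complement (A<->T, C<->G)
    win_r = win[rev][:, ::-1]
    win_r = np.where(win_r < 4, 3 - win_r, 4)
    win[rev] = win_r
    return win


def _site_kmer_counts(genome, positions, strands, k, flank):
    win = _window_matrix(genome, positions, strands, flank)
    center = flank
    counts: dict[tuple[str, int], int] = {}
    pw = 4 ** np.arange(k - 1, -1, -1)
    for s in range(max(0, center - k + 1), min(center + 1, win.shape[1] - k + 1)):
        sub = win[:, s : s + k]
        valid = ~(sub == 4).any(axis=1)
        codes = sub[valid].astype(np.int64) @ pw
        offset = center - s
        uniq, cnt = np.unique(codes, return_counts=True)
        for code, c in zip(uniq, cnt):
            counts[(_decode(int(code), k), offset)] = counts.get((_decode(int(code), k), offset), 0) + int(c)
    return counts, len(positions)


def _background_kmer_counts(genome, base, k, flank):
    """(k-mer, offset) counts over *all* genomic sites of ``base``, both strands."""
    code = _CODE[base]
    L = len(genome)
    fwd = np.array([_CODE[c] for c in genome.sequence], dtype=np.int8)
    pos_f = np.nonzero(fwd == code)[0] + 1
    comp = np.where(fwd < 4, 3 - fwd, 4)
    pos_r = np.nonzero(comp == code)[0] + 1
    positions = np.concatenate([pos_f, pos_r])
    strands = np.concatenate([np.repeat("+", len(pos_f)), np.repeat("-", len(pos_r))])
    counts, _ = _site_kmer_counts(genome, positions, strands, k, flank)
    return counts, len(positions)


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))
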