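"""CRISPR array structure, spacer/repeat methylation periodicity, and
self-targeting spacer mapping.

An array is parsed from a declared genomic region by greedily matching a
repeat consensus (Hamming distance, both orientations tried, one chosen per
array); the gaps between consecutive repeats are the spacers. The methylation
profile of an array asks whether spacers and repeats differ systematically —
e.g. spacers carrying asymmetric mCHH on both strands while repeats stay
unmethylated — via a label-permutation test on the spacer-minus-repeat mean
contrast. Spacer mapping slides each spacer over the full circular genome on
both strands to find any second occurrence (a self-targeting candidate),
annotating hits that fall in prophage intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeSequence, GenomicInterval, revcomp

log = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class CrisprArray:
    region: GenomicInterval
    repeat_consensus: str
    orientation: str  # strand of the consensus as matched: '+' or '-'
    repeats: list[GenomicInterval]
    spacers: list[GenomicInterval]
    repeat_mismatches: list[int]

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def spacer_sequences(self, genome: GenomeSequence) -> list[str]:
        return [genome.fetch(s.start, s.end) for s in self.spacers]


@dataclass(frozen=True)
class SpacerHit:
    spacer_index: int
    target: GenomicInterval
    strand: str
    mismatches: int
    in_prophage: bool


SPACER_LEN_RANGE = (15, 60)


def parse_array(
    genome: GenomeSequence,
    region: GenomicInterval,
    repeat_consensus: str,
    max_mismatch: int = 3,
) -> CrisprArray:
    """Locate repeats and spacers of one CRISPR array inside ``region``.

    The consensus is matched at every offset of the region in both
    orientations; the orientation with more repeats (ties: fewer total
    mismatches) is kept. Matches within ``max_mismatch`` are accepted
    greedily left-to-right without overlap. Gaps between consecutive repeats
    become spacers when their length is within 15-60 bp; an oversized gap is
    logged and excluded (a run-on gap is not sequence the array acquired).
    """
    if len(repeat_consensus) < 20:
        raise ValueError("repeat consensus must be >= 20 bp")
    if region.end > len(genome):
        raise ValueError("region exceeds genome length")
    seq = genome.fetch(region.start, region.end)
    best = None
    for orient, consensus in (("+", repeat_consensus.upper()), ("-", revcomp(repeat_consensus.upper()))):
        hits = _greedy_repeat_scan(seq, consensus, max_mismatch)
        score = (len(hits), -sum(mm for _, mm in hits))
        if best is None or score > best[0]:
            best = (score, orient, hits)
    _, orientation, hits = best
    if not hits:
        raise ValueError("no repeat occurrence found in region")

    rlen = len(repeat_consensus)
    repeats, mismatches = [], []
    for off, mm in hits:
        start = region.start + off
        repeats.append(GenomicInterval(genome.name, start, start + rlen - 1, orientation, "repeat"))
        mismatches.append(mm)
    spacers = []
    lo, hi = SPACER_LEN_RANGE
    for a, b in zip(repeats, repeats[1:]):
        gap_start, gap_end = a.end + 1, b.start - 1
        gap_len = gap_end - gap_start + 1
        if lo <= gap_len <= hi:
            spacers.append(
                GenomicInterval(genome.name, gap_start, gap_end, ".", f"spacer_{len(spacers) + 1}")
            )
        else:
            log.warning(
                "gap of %d bp between repeats at %d and %d outside [%d, %d]; array split here",
                gap_len, a.start, b.start, lo, hi,
            )
    return CrisprArray(region, repeat_consensus.upper(), orientation, repeats, spacers, mismatches)


def _greedy_repeat_scan(seq: str, consensus: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Non-overlapping (offset, mismatches) repeat matches, left to right.

    At each cursor position the best (fewest-mismatch) acceptable match in
    the next unmatched stretch is taken, preferring earlier offsets on ties,
    so a mismatch-carrying repeat cannot shadow a cleaner one just after it.
    """
    dists = _hamming_profile(seq, consensus)
    n = len(dists)
    rlen = len(consensus)
    hits = []
    i = 0
    while i < n:
        if dists[i] <= max_mismatch:
            # candidate window: offsets overlapping a match starting at i
            j_end = min(i + rlen, n)
            window = dists[i:j_end]
            j = i + int(np.argmin(window))
            if dists[j] < dists[i]:
                i = j
            hits.append((i, int(dists[i])))
            i += rlen
        else:
            i += 1
    return hits


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _hamming_profile(seq: str, query: str) -> np.ndarray:
    """Hamming distance of ``query`` against every offset of ``seq``."""
    s = _encode(seq)
    q = _encode(query)
    if len(s) < len(q):
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(s, len(q))
    return np.count_nonzero(windows != q, axis=1)


def array_methylation_profile(
    array: CrisprArray,
    records: pd.DataFrame,
    context: str = "CHH",
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-element methylation means and the spacer-vs-repeat contrast.

    For every repeat and spacer, per strand, the mean called fraction of
    ``context`` sites inside the element is reported. The periodicity
    statistic is T = mean over spacer elements - mean over repeat elements
    (element means strand-pooled, elements as units); its one-sided p-value
    comes from >= ``n_permutations`` seeded shuffles of the element labels.
    Elements without called sites are reported as missing and excluded from
    T with a warning.
    """
    if array.n_spacers == 0:
        raise ValueError("array has no spacers")
    sub = records[records["context"] == context]
    pos = sub["position"].to_numpy(np.int64)
    frac = sub["fraction"].to_numpy(float)
    strand = sub["strand"].to_numpy()

    rows = []
    element_means = []  # (label, pooled mean or nan)
    for kind, elements in (("repeat", array.repeats), ("spacer", array.spacers)):
        for idx, el in enumerate(elements, 1):
            inside = (pos >= el.start) & (pos <= el.end)
            pooled = float(frac[inside].mean()) if inside.any() else np.nan
            for st in ("+", "-"):
                m = inside & (strand == st)
                rows.append(
                    {
                        "element": kind,
                        "index": idx,
                        "start": el.start,
                        "end": el.end,
                        "strand": st,
                        "n_sites": int(m.sum()),
                        "mean_fraction": float(frac[m].mean()) if m.any() else np.nan,
                    }
                )
            element_means.append((kind, pooled))

    labels = np.array([k for k, _ in element_means])
    means = np.array([v for _, v in element_means])
    ok = ~np.isnan(means)
    if (~ok).any():
        log.warning("%d array elements had no called %s sites; excluded from T", int((~ok).sum()), context)
    labels, means = labels[ok], means[ok]
    is_spacer = labels == "spacer"
    if is_spacer.all() or (~is_spacer).all():
        T, pval = np.nan, np.nan
    else:
        T = float(means[is_spacer].mean() - means[~is_spacer].mean())
        rng = np.random.default_rng(seed)
        n_sp = int(is_spacer.sum())
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(means))
            t_star = means[perm[:n_sp]].mean() - means[perm[n_sp:]].mean()
            if t_star >= T:
                count += 1
        pval = (1 + count) / (1 + n_permutations)
    return pd.DataFrame(rows), {"T": T, "p_value": pval, "n_elements": int(ok.sum())}


def map_spacers(
    array: CrisprArray,
    genome: GenomeSequence,
    prophages: list[GenomicInterval] | None = None,
    max_mismatch: int = 2,
) -> list[SpacerHit]:
    """Map every spacer against both strands of the (circular) genome.

    Hamming sliding-window at every offset, wrapping the origin; hits inside
    the source array region are removed (the spacer's own position is not a
    self-target). Hits are flagged ``in_prophage`` when overlapping any
    prophage interval.
    """
    spacer_seqs = array.spacer_sequences(genome)
    if not spacer_seqs:
        raise ValueError("array has no spacers to map")
    prophages = prophages or []
    L = len(genome)
    seq = genome.sequence
    hits: list[SpacerHit] = []
    for si, sp in enumerate(spacer_seqs, 1):
        k = len(sp)
        ext = seq + seq[: k - 1] if genome.circular else seq
        for strand, query in (("+", sp), ("-", revcomp(sp))):
            dists = _hamming_profile(ext, query)
            for off in np.nonzero(dists <= max_mismatch)[0]:
                start = int(off) + 1
                end = start + k - 1  # may exceed L when wrapping; interval kept unwrapped
                iv = GenomicInterval(genome.name, start, min(end, L), strand, f"spacer_{si}_hit")
                if _overlaps_region(start, end, array.region, L, genome.circular):
                    continue
                in_pp = any(
                    _intervals_overlap(start, end, p.start, p.end, L, genome.circular)
                    for p in prophages
                )
                hits.append(SpacerHit(si, iv, strand, int(dists[off]), in_pp))
    return hits


def _intervals_overlap(a1, a2, b1, b2, L, circular):
    if not circular:
        return a1 <= b2 and b1 <= a2
    pts_a = {((p - 1) % L) for p in range(a1, a2 + 1)} if a2 - a1 < L else set(range(L))
    return any(((p - 1) % L) in pts_a for p in range(b1, b2 + 1))


def _overlaps_region(start, end, region: GenomicInterval, L, circular):
    return _intervals_overlap(start, end, region.start, region.end, L, circular)
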