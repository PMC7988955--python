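"""Strand-aware enumeration of methylation-context sites.

Five contexts are scanned:

* **Dam** — the adenine of a 5'-GATC-3' occurrence. GATC is palindromic, so
  one duplex locus carries one scorable A per strand.
* **Dcm** — the second cytosine of a 5'-CCWGG-3' (W = A/T) occurrence. The
  motif *set* {CCAGG, CCTGG} is self-complementary: every forward occurrence
  is simultaneously a reverse-strand occurrence of the partner motif, so one
  duplex locus again yields one scorable C per strand.
* **CpG / CHG / CHH** — the trinucleotide cytosine contexts (H = A/C/T),
  assigned with precedence CpG > CHG > CHH. Cytosines lying inside a Dcm
  occurrence are claimed by Dcm and never double-labelled.

Positions are 1-based on the forward strand for both strands; a reverse-strand
site's ``position`` is the forward coordinate of the base whose complement is
scored. ``duplex_locus`` is the forward coordinate of the leftmost base of the
motif footprint, which collapses the two strands of a palindromic occurrence
onto one locus. On circular genomes motifs may span the origin; any window
containing N yields no site.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import GenomeSequence

H_BASES = frozenset("ACT")


@dataclass(frozen=True)
class ContextSite:
    contig: str
    position: int  # 1-based forward coordinate of the scorable base
    strand: str
    context: str
    duplex_locus: int  # forward coordinate of the motif footprint's left end


@dataclass(frozen=True)
class ContextCensus:
    """Per-context site and duplex-locus counts."""

    sites: dict
    duplex_loci: dict

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in sorted(set(self.sites) | set(self.duplex_loci)):
            rows.append(
                {
                    "context": ctx,
                    "n_sites": self.sites.get(ctx, 0),
                    "n_duplex_loci": self.duplex_loci.get(ctx, 0),
                }
            )
        return pd.DataFrame(rows, columns=["context", "n_sites", "n_duplex_loci"])


def _wrap(pos: int, L: int) -> int:
    """Map an extended-scan coordinate back onto [1, L]."""
    return (pos - 1) % L + 1


def scan_contexts(genome: GenomeSequence) -> list[ContextSite]:
    """Enumerate every context site on both strands of one chromosome."""
    seq = genome.sequence
    L = len(seq)
    name = genome.name
    # extend across the origin so motifs spanning it are seen exactly once
    ext = seq + seq[:4] if genome.circular and L >= 4 else seq

    sites: list[ContextSite] = []
    # (pos, strand) cytosines claimed by a Dcm footprint (no trinucleotide label)
    claimed: set[tuple[int, str]] = set()

    # --- Dam: GATC occurrences on the forward strand (palindromic)
    for m in re.finditer("(?=GATC)", ext[: L + 3] if genome.circular else ext):
        p = m.start() + 1  # leftmost G, 1-based
        if p > L:
            break
        sites.append(ContextSite(name, _wrap(p + 1, L), "+", "Dam", p))
        sites.append(ContextSite(name, _wrap(p + 2, L), "-", "Dam", p))

    # --- Dcm: CCWGG occurrences on the forward strand (self-complementary set)
    for m in re.finditer("(?=CC[AT]GG)", ext[: L + 4] if genome.circular else ext):
        p = m.start() + 1
        if p > L:
            break
        # scorable: second C of each strand's own 5'->3' reading
        sites.append(ContextSite(name, _wrap(p + 1, L), "+", "Dcm", p))
        sites.append(ContextSite(name, _wrap(p + 3, L), "-", "Dcm", p))
        # footprint cytosines on either strand are claimed by Dcm
        claimed.add((_wrap(p, L), "+"))
        claimed.add((_wrap(p + 1, L), "+"))
        claimed.add((_wrap(p + 3, L), "-"))
        claimed.add((_wrap(p + 4, L), "-"))

    # --- trinucleotide cytosine contexts, forward strand
    for i, b in enumerate(seq):
        if b != "C" or (i + 1, "+") in claimed:
            continue
        ctx, locus = _classify_forward(genome, i + 1)
        if ctx:
            sites.append(ContextSite(name, i + 1, "+", ctx, locus))

    # --- reverse strand: a cytosine on '-' sits where the forward base is G
    for i, b in enumerate(seq):
        if b != "G" or (i + 1, "-") in claimed:
            continue
        ctx, locus = _classify_reverse(genome, i + 1)
        if ctx:
            sites.append(ContextSite(name, i + 1, "-", ctx, locus))

    sites.sort(key=lambda s: (s.position, s.strand, s.context))
    return sites


def _next_bases(genome: GenomeSequence, pos: int, step: int, n: int) -> str | None:
    """n bases downstream of pos (exclusive) walking by step; None if off-end."""
    L = len(genome)
    out = []
    for k in range(1, n + 1):
        p = pos + step * k
        if not genome.circular and not 1 <= p <= L:
            return None
        out.append(genome.base(p))
    return "".join(out)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _classify_forward(genome: GenomeSequence, pos: int) -> tuple[str | None, int]:
    """Trinucleotide context of a forward-strand C at ``pos``."""
    L = len(genome)
    two = _next_bases(genome, pos, +1, 2)
    one = two[0] if two else _next_bases(genome, pos, +1, 1)
    if one == "G":
        return "CpG", pos
    if two is None or "N" in two:
        return None, pos
    if two[0] in H_BASES and two[1] == "G":
        return "CHG", pos
    if two[0] in H_BASES and two[1] in H_BASES:
        return "CHH", pos
    return None, pos


def _classify_reverse(genome: GenomeSequence, pos: int) -> tuple[str | None, int]:
    """Context of the reverse-strand C at forward position ``pos``.

    Downstream on '-' runs towards smaller forward coordinates; bases are
    complemented to read the reverse strand 5'->3'.
    """
    L = len(genome)
    raw2 = _next_bases(genome, pos, -1, 2)
    raw1 = raw2[0] if raw2 else _next_bases(genome, pos, -1, 1)
    one = _COMP[raw1] if raw1 else None
    if one == "G":
        # CG on the reverse strand == CG on the forward strand one base left
        return "CpG", _wrap(pos - 1, L) if genome.circular else pos - 1
    if raw2 is None:
        return None, pos
    two = "".join(_COMP[c] for c in raw2)
    if "N" in two:
        return None, pos
    left = _wrap(pos - 2, L) if genome.circular else pos - 2
    if two[0] in H_BASES and two[1] == "G":
        return "CHG", left
    if two[0] in H_BASES and two[1] in H_BASES:
        return "CHH", left
    return None, pos


def census(sites: list[ContextSite]) -> ContextCensus:
    """Count sites and distinct duplex loci per context.

    For palindromic contexts (Dam, Dcm, CpG) the duplex-locus count is the
    number of double-stranded motif occurrences; for the asymmetric CHH it
    simply counts distinct footprints per context.
    """
    n_sites: Counter = Counter()
    loci: dict[str, set] = {}
    for s in sites:
        n_sites[s.context] += 1
        loci.setdefault(s.context, set()).add(s.duplex_locus)
    return ContextCensus(
        sites=dict(n_sites), duplex_loci={c: len(v) for c, v in loci.items()}
    )


def sites_to_frame(sites: list[ContextSite]) -> pd.DataFrame:
    """Tabular view of a site list (one row per scorable base)."""
    return pd.DataFrame(
        [(s.contig, s.position, s.strand, s.context, s.duplex_locus) for s in sites],
        columns=["contig", "position", "strand", "context", "duplex_locus"],
    )
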