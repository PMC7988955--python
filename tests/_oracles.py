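"""Independent brute-force oracles used only by the tests.

The context oracle classifies every (position, strand) of a genome in
isolation by direct window inspection, without any of the scanning machinery
under test.
"""

from __future__ import annotations

from bactometh.io import GenomeSequence

DCM_SET = {"CCAGG", "CCTGG"}
H = set("ACT")
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _window(genome: GenomeSequence, start: int, n: int) -> str | None:
    """n-base forward-strand window starting at 1-based ``start``; None off-end."""
    L = len(genome)
    if genome.circular:
        return "".join(genome.sequence[(p - 1) % L] for p in range(start, start + n))
    if start < 1 or start + n - 1 > L:
        return None
    return genome.sequence[start - 1 : start + n - 1]


def brute_force_sites(genome: GenomeSequence) -> set[tuple]:
    """(position, strand, context, duplex_locus) for every site, one at a time."""
    L = len(genome)
    out = set()

    def norm(p):  # map any coordinate onto [1, L]
        return (p - 1) % L + 1 if genome.circular else p

    for i in range(1, L + 1):
        b = genome.sequence[i - 1]
        # --- Dam
        if b == "A" and _window(genome, i - 1, 4) == "GATC":
            out.add((i, "+", "Dam", norm(i - 1)))
        if b == "T" and _window(genome, i - 2, 4) == "GATC":
            out.add((i, "-", "Dam", norm(i - 2)))
        # --- Dcm scorable Cs (second C of each strand's own reading)
        if b == "C" and _window(genome, i - 1, 5) in DCM_SET:
            out.add((i, "+", "Dcm", norm(i - 1)))
        if b == "G" and _window(genome, i - 3, 5) in DCM_SET:
            out.add((i, "-", "Dcm", norm(i - 3)))
        # --- forward-strand cytosine trinucleotide contexts
        if b == "C" and not _in_dcm_footprint_fwd(genome, i):
            n1 = _window(genome, i + 1, 1)
            n2 = _window(genome, i + 2, 1)
            if n1 == "G":
                out.add((i, "+", "CpG", i))
            elif n1 in H and n2 == "G":
                out.add((i, "+", "CHG", i))
            elif n1 in H and n2 in H:
                out.add((i, "+", "CHH", i))
        # --- reverse-strand cytosines (forward base G), read 5'->3' on '-'
        if b == "G" and not _in_dcm_footprint_rev(genome, i):
            r1 = _window(genome, i - 1, 1)
            r2 = _window(genome, i - 2, 1)
            n1 = COMP[r1] if r1 else None
            n2 = COMP[r2] if r2 else None
            if n1 == "G":
                out.add((i, "-", "CpG", norm(i - 1)))
            elif n1 in H and n2 == "G":
                out.add((i, "-", "CHG", norm(i - 2)))
            elif n1 in H and n2 in H:
                out.add((i, "-", "CHH", norm(i - 2)))
    return out


def _in_dcm_footprint_fwd(genome, i):
    # forward-strand Cs of a CCWGG occurrence sit at offsets 0 and 1
    return _window(genome, i, 5) in DCM_SET or _window(genome, i - 1, 5) in DCM_SET


def _in_dcm_footprint_rev(genome, i):
    # reverse-strand Cs (forward Gs) of a CCWGG occurrence sit at offsets 3 and 4
    return _window(genome, i - 3, 5) in DCM_SET or _window(genome, i - 4, 5) in DCM_SET
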