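"""Readers, writers and the coordinate conventions shared by every module.

All internal coordinates are **1-based inclusive**, matching how bacterial
genome locations are printed in annotation reports (e.g. an array at
"638,577 bp - 639,957 bp").  BED and bedGraph output converts to 0-based
half-open at the boundary and nowhere else.

Methylation calls travel as a pandas DataFrame with columns
``contig, position, strand, base, context, coverage, fraction`` — one row per
called site, ``fraction`` being the per-site proportion of reads carrying the
modification.  :func:`read_methylation_table` validates the frame against the
record invariants; downstream modules assume a validated frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
#: Recognised methylation contexts. Dam marks N6-methyladenine in GATC;
#: the rest are cytosine contexts (Dcm = CCWGG; CpG/CHG/CHH trinucleotide).
CONTEXTS = ("CpG", "CHG", "CHH", "Dcm", "Dam")

METH_COLUMNS = ["contig", "position", "strand", "base", "context", "coverage", "fraction"]


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}, optionally circular."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.name!r}")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"illegal character {seq[pos]!r} at position {pos + 1} in record {self.name!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position, wrapping the origin when circular."""
        L = len(self.sequence)
        if self.circular:
            return self.sequence[(position - 1) % L]
        if not 1 <= position <= L:
            raise IndexError(f"position {position} outside linear genome of length {L}")
        return self.sequence[position - 1]

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive interval; wraps when circular."""
        L = len(self.sequence)
        if start > end:
            raise ValueError("start > end")
        if 1 <= start and end <= L:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise IndexError(f"interval {start}-{end} outside linear genome of length {L}")
        return "".join(self.sequence[(p - 1) % L] for p in range(start, end + 1))


@dataclass(frozen=True)
class GeneFeature:
    """A stranded 1-based-inclusive gene interval from a GFF3 file."""

    contig: str
    start: int
    end: int
    strand: str
    feature_id: str
    feature_type: str = "CDS"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"bad interval {self.start}-{self.end} for feature {self.feature_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled 1-based inclusive interval, strand optional ('.')."""

    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} for {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start <= other.end and other.start <= self.end


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# readers


def read_genome(path, circular: bool = True) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Sequences are uppercased; any character outside {A,C,G,T,N} raises with
    its position. Most downstream operations expect a single chromosome.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(GenomeSequence(name=rec.id, sequence=str(rec.seq), circular=circular))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def read_annotation(path, keep_types: set[str] = frozenset({"CDS"})) -> list[GeneFeature]:
    """Parse gene features from GFF3 (1-based inclusive, per the standard).

    Only ``keep_types`` feature types are kept.  Records with strand '.' are
    dropped with a warning — a strand-resolved analysis cannot use them.
    The feature id is taken from the ID attribute, falling back to
    locus_tag, then to a positional tag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    keep_types = set(keep_types)
    feats: list[GeneFeature] = []
    n_unstranded = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            if ftype not in keep_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}")
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            if strand == ".":
                n_unstranded += 1
                continue
            fid = _gff_attr(attrs, "ID") or _gff_attr(attrs, "locus_tag") or f"{ftype}_{lineno}"
            feats.append(GeneFeature(contig, start_i, end_i, strand, fid, ftype))
    if n_unstranded:
        log.warning("dropped %d unstranded ('.') features from %s", n_unstranded, path)
    return feats


def _gff_attr(attrs: str, key: str) -> str | None:
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith(key + "="):
            return kv[len(key) + 1 :]
    return None


def read_methylation_table(path) -> pd.DataFrame:
    """Read the per-site modification TSV into a validated DataFrame.

    Expected header: ``contig position strand base context coverage fraction``
    (tab-separated). Fractions must lie in [0,1], coverage must be
    non-negative, contexts must belong to the known enumeration, and adenine
    records must carry the Dam context.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return validate_methylation(df[METH_COLUMNS], source=str(path))


def validate_methylation(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    """Enforce methylation-record invariants; returns the frame unchanged."""

    def _fail(mask: pd.Series, msg: str):
        if mask.any():
            # +2: 1 for the header line, 1 for 0-based index
            lines = (df.index[mask] + 2).tolist()[:5]
            raise ValueError(f"{source}: {msg} (file line(s) {lines})")

    frac = pd.to_numeric(df["fraction"], errors="coerce")
    _fail(frac.isna(), "non-numeric fraction")
    _fail((frac < 0) | (frac > 1), "fraction outside [0, 1]")
    cov = pd.to_numeric(df["coverage"], errors="coerce")
    _fail(cov.isna() | (cov < 0), "coverage negative or non-numeric")
    _fail(~df["context"].isin(CONTEXTS), f"unknown context (expected one of {CONTEXTS})")
    _fail(~df["strand"].isin(["+", "-"]), "strand must be '+' or '-'")
    _fail(~df["base"].isin(["A", "C"]), "modified base must be A or C")
    _fail((df["base"] == "A") & (df["context"] != "Dam"), "adenine records must be Dam context")
    _fail((df["base"] == "C") & (df["context"] == "Dam"), "cytosine records cannot be Dam context")
    out = df.copy()
    out["position"] = out["position"].astype(np.int64)
    out["coverage"] = cov.astype(np.int64)
    out["fraction"] = frac.astype(float)
    return out


def write_methylation_table(df: pd.DataFrame, path) -> None:
    """Write a methylation frame in the TSV dialect read back by
    :func:`read_methylation_table` (lossless round-trip)."""
    validate_methylation(df)[METH_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval tracks


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """Internal 1-based inclusive -> BED 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """BED 0-based half-open -> internal 1-based inclusive."""
    return start + 1, end


def write_track(table: pd.DataFrame, path, fmt: str = "bedGraph") -> None:
    """Write sorted intervals as BED or bedGraph.

    ``table`` needs columns contig/start/end (internal convention) plus
    ``value`` for bedGraph or ``label`` for BED.  Rows must be sorted by
    start; bedGraph intervals must not overlap.
    """
    if fmt not in ("BED", "bedGraph"):
        raise ValueError(f"unknown track format {fmt!r}")
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    if np.any(np.diff(starts) < 0):
        raise ValueError("intervals must be sorted by start")
    if fmt == "bedGraph" and np.any(starts[1:] <= ends[:-1]):
        raise ValueError("bedGraph intervals must not overlap")
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            b0, b1 = to_bed_interval(row.start, row.end)
            if fmt == "bedGraph":
                fh.write(f"{row.contig}\t{b0}\t{b1}\t{row.value:g}\n")
            else:
                label = getattr(row, "label", ".")
                fh.write(f"{row.contig}\t{b0}\t{b1}\t{label}\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file into internal 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            start, end = from_bed_interval(int(cols[1]), int(cols[2]))
            label = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 else "."
            out.append(GenomicInterval(cols[0], start, end, strand, label))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda v: (v.contig, v.start)):
            b0, b1 = to_bed_interval(iv.start, iv.end)
            fh.write(f"{iv.contig}\t{b0}\t{b1}\t{iv.label or '.'}\t0\t{iv.strand}\n")
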