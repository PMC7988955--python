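"""Synthetic genomes, annotations, CRISPR arrays and methylomes.

The generator emulates the statistical structure of a closed ~3.8-Mb,
45%-GC bacterial chromosome profiled for base modifications:

* per-context modification fractions drawn from Beta distributions whose
  default means mirror the empirical per-context levels (Dam ~76%, CpG ~4%,
  Dcm ~4%, CHH ~17%) with Poisson read coverage at the empirical depths;
* a genome segment where reverse-strand mCHH is depleted (multiplier on the
  Beta mean), paired with reverse-strand-biased gene placement in the same
  segment;
* a small planted gene cluster with elevated promoter mCpG;
* CRISPR arrays whose spacers carry mCHH while repeats stay unmethylated;
* planted methylated sequence motifs (e.g. GAACT adenines) for de novo
  motif discovery.

Everything is deterministic under a fixed seed, and every planted structure
is returned in a truth bundle so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contexts
from .io import (
    GeneFeature,
    GenomeSequence,
    GenomicInterval,
    revcomp,
    write_methylation_table,
)
from .metaplot import MetaplotMatrix

#: Direct-repeat sequences of the two CRISPR arrays used by the dri13 preset.
REPEAT_ARRAY1 = "GTTGCAATGCCTAGCTCAGAGGTTTAAAGACTGAGAC"
REPEAT_ARRAY2 = "CTTTCAGTCCCCATGTATCGGGTCTATTCAATGGAAC"

_BASES = np.array(list("ACGT"))


@dataclass
class MethylomeModel:
    """Beta/Poisson site-level model of a bacterial methylome.

    ``context_means`` are the Beta means per context (reverse-strand CHH may
    differ via ``chh_rev_mean``); ``kappa`` is the shared Beta concentration
    (np.inf collapses every fraction onto its mean); ``coverage_lambda`` the
    Poisson read-depth means.
    """

    context_means: dict = field(
        default_factory=lambda: {"CpG": 0.0428, "CHG": 0.10, "CHH": 0.1741, "Dcm": 0.0381, "Dam": 0.764}
    )
    chh_rev_mean: float = 0.1739
    kappa: float = 5.0
    coverage_lambda: dict = field(
        default_factory=lambda: {"CpG": 121, "CHG": 54, "CHH": 54, "Dcm": 94, "Dam": 42}
    )
    # reverse-strand CHH depletion: (interval, multiplier on the Beta mean)
    depletion_region: GenomicInterval | None = None
    depletion_multiplier: float = 0.25
    # promoter mCpG boost for a planted gene cluster
    cluster_gene_ids: list = field(default_factory=list)
    promoter_boost: float = 0.4
    promoter_upstream: int = 200
    promoter_downstream: int = 50
    # CRISPR element CHH means (None: leave the background model in place)
    spacer_chh_mean: float | None = 0.4
    repeat_chh_mean: float | None = 0.02
    seed: int = 0

    def __post_init__(self):
        for c, mu in self.context_means.items():
            if not 0 <= mu <= 1:
                raise ValueError(f"mean for {c} outside [0,1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    length: int,
    gc: float = 0.45,
    seed: int = 0,
    plant: dict[str, int] | None = None,
    circular: bool = True,
    name: str = "synthchr",
) -> tuple[GenomeSequence, dict]:
    """I.i.d. genome at a target GC, with optional motif-count planting.

    ``plant`` maps a motif (forward-strand occurrences, both strands for
    palindromes implicitly) to a target occurrence count; occurrences are
    added by substitution at random loci or removed by resampling until each
    count is within +/-2% (at least +/-1) of target. Returns the genome and a
    truth dict with the final motif loci.
    """
    if length < 10_000:
        raise ValueError("length must be >= 10 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=length, p=p)
    arr = _BASES[seq].copy()

    truth: dict = {"length": length, "gc": gc, "seed": seed, "motif_loci": {}}
    protected: set[int] = set()
    for motif, target in (plant or {}).items():
        loci = _plant_motif(arr, motif, target, rng, protected)
        truth["motif_loci"][motif] = sorted(int(x) for x in loci)
        for lo in loci:
            protected.update(range(lo, lo + len(motif)))
    genome = GenomeSequence(name=name, sequence="".join(arr), circular=circular)
    truth["observed_gc"] = (genome.sequence.count("G") + genome.sequence.count("C")) / length
    return genome, truth


def _find_occurrences(s: str, motif: str) -> list[int]:
    return [m.start() for m in re.finditer(f"(?={motif})", s)]


def _plant_motif(arr: np.ndarray, motif: str, target: int, rng, protected: set[int]) -> list[int]:
    """Adjust forward-strand occurrences of ``motif`` to ``target`` +/- 2%."""
    m = len(motif)
    tol = max(1, int(round(0.02 * target)))
    for _ in range(200):
        s = "".join(arr)
        occ = _find_occurrences(s, motif)
        diff = len(occ) - target
        if abs(diff) <= tol:
            return occ
        if diff > 0:  # too many: destroy a random excess occurrence
            removable = [o for o in occ if not any(o + j in protected for j in range(m))]
            if not removable:
                raise ValueError(f"cannot reach target count for motif {motif}")
            for o in rng.choice(removable, size=min(diff, len(removable)), replace=False):
                j = int(rng.integers(m))
                choices = [b for b in "ACGT" if b != motif[j]]
                arr[o + j] = choices[int(rng.integers(3))]
        else:  # too few: write the motif at random free loci
            need = -diff
            cand = rng.integers(0, len(arr) - m, size=4 * need)
            placed = 0
            for o in cand:
                o = int(o)
                if any(o + j in protected for j in range(m)):
                    continue
                arr[o : o + m] = list(motif)
                placed += 1
                if placed >= need:
                    break
    raise ValueError(f"motif planting for {motif} did not converge to {target}")


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    genome: GenomeSequence,
    n_genes: int,
    strand_bias_by_bin: list[float] | float = 0.5,
    bias_bin_width: int = 1_000_000,
    length_mean: float = 900.0,
    length_sd: float = 250.0,
    length_min: int = 150,
    seed: int = 0,
) -> tuple[list[GeneFeature], dict]:
    """Place non-overlapping genes with per-bin strand bias.

    ``strand_bias_by_bin`` is the forward-strand probability, either global
    or one value per ``bias_bin_width`` bin of the gene's start coordinate.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    lengths = np.maximum(rng.normal(length_mean, length_sd, size=n_genes), length_min).astype(int)
    total = int(lengths.sum())
    if total >= L:
        raise ValueError(f"cannot place {n_genes} genes of total length {total} on {L} bp")
    # distribute the slack as random intergenic gaps (multinomial split)
    slack = L - total
    gaps = rng.multinomial(slack, np.ones(n_genes + 1) / (n_genes + 1))
    if isinstance(strand_bias_by_bin, (int, float)):
        bias = None
        p_global = float(strand_bias_by_bin)
    else:
        bias = list(strand_bias_by_bin)

    genes = []
    cursor = 1 + int(gaps[0])
    for i in range(n_genes):
        start = cursor
        end = start + int(lengths[i]) - 1
        if end > L:
            break
        if bias is None:
            p_fwd = p_global
        else:
            b = min((start - 1) // bias_bin_width, len(bias) - 1)
            p_fwd = bias[b]
        strand = "+" if rng.random() < p_fwd else "-"
        genes.append(GeneFeature(genome.name, start, end, strand, f"gene_{i + 1:05d}", "CDS"))
        cursor = end + 1 + int(gaps[i + 1])
    truth = {
        "n_genes": len(genes),
        "seed": seed,
        "strand_bias_by_bin": bias if bias is not None else p_global,
    }
    return genes, truth


def write_gff3(genes: list[GeneFeature], path, contig_lengths: dict[str, int] | None = None) -> None:
    """Minimal GFF3 writer for simulated annotations."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, clen in (contig_lengths or {}).items():
            fh.write(f"##sequence-region {contig} 1 {clen}\n")
        for g in sorted(genes, key=lambda x: (x.contig, x.start)):
            fh.write(
                f"{g.contig}\tbactometh\t{g.feature_type}\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.feature_id}\n"
            )


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CRISPR planting


def plant_crispr(
    genome: GenomeSequence,
    repeat_seq: str,
    n_repeats: int,
    spacer_len: int = 37,
    location: int = 1,
    seed: int = 0,
    occupied: list[GenomicInterval] | None = None,
) -> tuple[GenomeSequence, dict]:
    """Write an alternating repeat/spacer block into the genome.

    Spacers are random, mutually distinct sequences. The edited genome and
    the truth intervals (1-based inclusive) of every element are returned.
    Raises when the block would overlap any ``occupied`` interval.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    rng = np.random.default_rng(seed)
    spacers = set()
    while len(spacers) < n_repeats - 1:
        spacers.add("".join(rng.choice(list("ACGT"), size=spacer_len)))
    spacers = sorted(spacers)
    rng.shuffle(spacers := list(spacers))

    block_parts, repeat_ivs, spacer_ivs = [], [], []
    pos = location
    for i in range(n_repeats):
        block_parts.append(repeat_seq)
        repeat_ivs.append((pos, pos + len(repeat_seq) - 1))
        pos += len(repeat_seq)
        if i < n_repeats - 1:
            block_parts.append(spacers[i])
            spacer_ivs.append((pos, pos + spacer_len - 1))
            pos += spacer_len
    block = "".join(block_parts)
    end = location + len(block) - 1
    if end > len(genome):
        raise ValueError("array block exceeds genome length")
    region = GenomicInterval(genome.name, location, end, ".", "crispr_array")
    for iv in occupied or []:
        if region.overlaps(iv):
            raise ValueError(f"array region overlaps occupied interval {iv.label!r}")
    seq = genome.sequence[: location - 1] + block + genome.sequence[end:]
    edited = GenomeSequence(genome.name, seq, genome.circular)
    truth = {
        "region": (location, end),
        "repeat_seq": repeat_seq,
        "repeats": repeat_ivs,
        "spacers": spacer_ivs,
        "seed": seed,
    }
    return edited, truth


# ---------------------------------------------------------------------------
# methylome


def simulate_methylome(
    genome: GenomeSequence,
    model: MethylomeModel,
    genes: list[GeneFeature] | None = None,
    array_truths: list[dict] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-site modification calls for every context site of the genome.

    Each site scanned by the context scanner receives Poisson coverage and a
    Beta fraction whose mean is the context default modified by: the
    reverse-strand CHH depletion multiplier inside the depletion region; the
    promoter mCpG boost for cluster genes; and spacer/repeat CHH means inside
    planted CRISPR arrays.
    """
    rng = np.random.default_rng(model.seed)
    sites = contexts.scan_contexts(genome)
    n = len(sites)
    position = np.array([s.position for s in sites], dtype=np.int64)
    strand = np.array([s.strand for s in sites])
    context = np.array([s.context for s in sites])

    mu = np.array([model.context_means[c] for c in context])
    chh = context == "CHH"
    mu[chh & (strand == "-")] = model.chh_rev_mean

    if model.depletion_region is not None:
        r = model.depletion_region
        in_dep = (position >= r.start) & (position <= r.end)
        sel = chh & (strand == "-") & in_dep
        mu[sel] = mu[sel] * model.depletion_multiplier

    cluster_ids = set(model.cluster_gene_ids)
    if cluster_ids and genes:
        cpg = context == "CpG"
        boost = np.zeros(n, dtype=bool)
        for g in genes:
            if g.feature_id not in cluster_ids:
                continue
            if g.strand == "+":
                lo, hi = g.start - model.promoter_upstream, g.start + model.promoter_downstream
            else:
                lo, hi = g.end - model.promoter_downstream, g.end + model.promoter_upstream
            boost |= (position >= lo) & (position <= hi)
        sel = cpg & boost
        mu[sel] = np.minimum(mu[sel] + model.promoter_boost, 1.0)

    for tr in array_truths or []:
        if model.spacer_chh_mean is not None:
            for a, b in tr["spacers"]:
                mu[chh & (position >= a) & (position <= b)] = model.spacer_chh_mean
        if model.repeat_chh_mean is not None:
            for a, b in tr["repeats"]:
                mu[chh & (position >= a) & (position <= b)] = model.repeat_chh_mean

    lam = np.array([model.coverage_lambda[c] for c in context])
    coverage = rng.poisson(lam)
    fraction = _beta_at_mean(mu, model.kappa, rng)

    records = pd.DataFrame(
        {
            "contig": genome.name,
            "position": position,
            "strand": strand,
            "base": np.where(context == "Dam", "A", "C"),
            "context": context,
            "coverage": coverage,
            "fraction": fraction,
        }
    ).sort_values(["position", "strand"], kind="stable").reset_index(drop=True)
    truth = {
        "n_sites": n,
        "context_means": dict(model.context_means),
        "chh_rev_mean": model.chh_rev_mean,
        "kappa": model.kappa,
        "seed": model.seed,
    }
    return records, truth


def _beta_at_mean(mu: np.ndarray, kappa: float, rng) -> np.ndarray:
    mu = np.clip(mu, 1e-9, 1 - 1e-9)
    if np.isinf(kappa):
        return mu.copy()
    return rng.beta(mu * kappa, (1 - mu) * kappa)


def simulate_denovo_calls(
    genome: GenomeSequence,
    base: str = "A",
    motif_means: dict[str, tuple[int, float]] | None = None,
    background_mean: float = 0.02,
    kappa: float = np.inf,
    coverage_lambda: float = 40.0,
    uniform_null: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-base de novo modification calls for motif discovery.

    Emits one record for *every* genomic position of ``base`` on both
    strands. ``motif_means`` maps a motif to (offset of the modified base
    within the motif, Beta mean at matching positions); all other positions
    use ``background_mean``. ``uniform_null=True`` replaces all means with
    U(0,1) fractions (a fully unstructured null). The context column carries
    the base's canonical channel label (Dam for A, CHH for C), which the
    motif-discovery selector ignores.
    """
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = {"A": "T", "C": "G"}[base]
    pos_f = np.nonzero(arr == ord(base))[0] + 1
    pos_r = np.nonzero(arr == ord(comp))[0] + 1
    position = np.concatenate([pos_f, pos_r])
    strand = np.concatenate([np.repeat("+", len(pos_f)), np.repeat("-", len(pos_r))])

    mu = np.full(len(position), background_mean)
    ext = seq + seq[: 12] if genome.circular else seq
    for motif, (offset, mean) in (motif_means or {}).items():
        mod_f = {m.start() + offset + 1 for m in re.finditer(f"(?={motif})", ext) if m.start() < L}
        rc = revcomp(motif)
        off_r = len(motif) - 1 - offset
        mod_r = {m.start() + off_r + 1 for m in re.finditer(f"(?={rc})", ext) if m.start() < L}
        mod_f = {(p - 1) % L + 1 for p in mod_f}
        mod_r = {(p - 1) % L + 1 for p in mod_r}
        mask_f = np.isin(position, sorted(mod_f)) & (strand == "+")
        mask_r = np.isin(position, sorted(mod_r)) & (strand == "-")
        mu[mask_f | mask_r] = mean

    if uniform_null:
        fraction = rng.uniform(0, 1, size=len(position))
    else:
        fraction = _beta_at_mean(mu, kappa, rng)
    return pd.DataFrame(
        {
            "contig": genome.name,
            "position": position,
            "strand": strand,
            "base": base,
            "context": "Dam" if base == "A" else "CHH",
            "coverage": rng.poisson(coverage_lambda, size=len(position)),
            "fraction": fraction,
        }
    ).sort_values(["position", "strand"], kind="stable").reset_index(drop=True)


def simulate_records_at_means(
    n_per_context: int, model: MethylomeModel, seed: int = 0
) -> pd.DataFrame:
    """Records drawn straight from the Beta/Poisson site model, one block of
    ``n_per_context`` sites per context (positions are synthetic placeholders).

    The direct route for parameter-recovery studies: no genome scan, just the
    fraction/coverage model feeding the summary statistics.
    """
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for ctx, mu in model.context_means.items():
        n = n_per_context
        frames.append(
            pd.DataFrame(
                {
                    "contig": "sim",
                    "position": np.arange(offset + 1, offset + n + 1),
                    "strand": "+",
                    "base": "A" if ctx == "Dam" else "C",
                    "context": ctx,
                    "coverage": rng.poisson(model.coverage_lambda[ctx], size=n),
                    "fraction": _beta_at_mean(np.full(n, mu), model.kappa, rng),
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# promoter-matrix simulation (cluster-recovery studies)


def simulate_promoter_matrix(
    n_genes: int = 1000,
    n_planted: int = 20,
    delta: float = 0.3,
    base_mean: float = 0.05,
    kappa: float = 5.0,
    flank: int = 1000,
    body_bins: int = 100,
    flank_bins: int = 50,
    missing_rate: float = 0.2,
    seed: int = 0,
) -> tuple[MetaplotMatrix, list[str]]:
    """A metaplot matrix with a planted promoter-methylated gene cluster.

    Planted genes get Beta(mean base_mean + delta) in the promoter-window
    columns; everything else is Beta(base_mean). A ``missing_rate`` share of
    cells is masked NaN. Returns the matrix and the planted gene ids.
    """
    rng = np.random.default_rng(seed)
    n_cols = 2 * flank_bins + body_bins
    vals = _beta_at_mean(np.full((n_genes, n_cols), base_mean), kappa, rng)
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    planted = sorted(rng.choice(n_genes, size=n_planted, replace=False).tolist())
    mat = MetaplotMatrix(vals, gene_ids, "CpG", flank, body_bins, flank_bins)
    from .metaplot import promoter_columns  # local import avoids cycle at module load

    cols = promoter_columns(mat)
    boosted = _beta_at_mean(
        np.full((n_planted, len(cols)), min(base_mean + delta, 1.0)), kappa, rng
    )
    vals[np.ix_(planted, cols)] = boosted
    mask = rng.random((n_genes, n_cols)) < missing_rate
    vals[mask] = np.nan
    return mat, [gene_ids[i] for i in planted]


# ---------------------------------------------------------------------------
# dri13 preset: a full desk-scale dataset


#: Forward-strand gene proportions per Mb, echoing the strongly
#: reverse-biased second megabase of the reference chromosome.
DRI13_STRAND_BIAS = [0.695, 0.173, 0.392, 0.818]

DRI13_PROPHAGE_STARTS = [566_157, 1_114_566, 2_229_417, 3_768_183]
DRI13_PROPHAGE_LENGTHS = [14_900, 22_300, 20_500, 36_100]


def dri13_model(seed: int = 0, **overrides) -> MethylomeModel:
    """The default methylome model of the dri13 preset."""
    return MethylomeModel(seed=seed, **overrides)


def simulate_dataset(
    outdir=None,
    seed: int = 7,
    scale: float = 0.1,
    gc: float = 0.45,
    n_cluster_genes: int = 45,
) -> dict:
    """Generate the full desk-scale dataset (preset ``dri13``).

    A circular genome of 3.8 Mb x ``scale`` at 45% GC with two planted
    CRISPR arrays (19 and 76 repeats, the two reference direct-repeat
    sequences), strand-biased gene placement per scaled Mb, a reverse-strand
    CHH depletion segment in the second scaled megabase, a 45-gene cluster
    with boosted promoter mCpG, and a full per-site methylome. Returns a
    dict with all in-memory objects and the truth bundle; when ``outdir`` is
    given, also writes genome.fa, genes.gff3, meth.tsv, arrays.bed,
    prophages.bed and truth.json.
    """
    rng = np.random.default_rng(seed)
    L = int(round(3_805_411 * scale))
    mb = int(round(1_000_000 * scale))
    genome, gtruth = simulate_genome(L, gc=gc, seed=seed, name="dri13sim")

    # CRISPR arrays at the scaled reference locations
    arrays = []
    arr_specs = [
        (REPEAT_ARRAY1, 19, int(round(638_577 * scale))),
        (REPEAT_ARRAY2, 76, int(round(1_393_508 * scale))),
    ]
    occupied: list[GenomicInterval] = []
    for i, (rep, n_rep, loc) in enumerate(arr_specs, 1):
        genome, tr = plant_crispr(
            genome, rep, n_rep, spacer_len=37, location=loc,
            seed=int(rng.integers(2**31)), occupied=occupied,
        )
        arrays.append(tr)
        occupied.append(GenomicInterval(genome.name, *tr["region"], ".", f"array_{i}"))

    genes, atruth = simulate_annotation(
        genome,
        n_genes=int(round(3884 * scale)),
        strand_bias_by_bin=DRI13_STRAND_BIAS,
        bias_bin_width=mb,
        seed=int(rng.integers(2**31)),
    )
    # keep annotation clear of the arrays
    genes = [g for g in genes if not any(o.overlaps(GenomicInterval(g.contig, g.start, g.end)) for o in occupied)]

    n_cluster = min(n_cluster_genes, max(1, len(genes) // 4))  # tiny scales carry fewer genes
    cluster_ids = [g.feature_id for g in rng.choice(genes, size=n_cluster, replace=False)]
    model = MethylomeModel(
        depletion_region=GenomicInterval(genome.name, mb + 1, 2 * mb, ".", "chh_rev_depleted"),
        cluster_gene_ids=cluster_ids,
        seed=int(rng.integers(2**31)),
    )
    records, mtruth = simulate_methylome(genome, model, genes=genes, array_truths=arrays)

    prophages = [
        GenomicInterval(
            genome.name,
            max(1, int(round(s * scale))),
            min(L, int(round(s * scale)) + max(1000, int(round(l * scale))) - 1),
            ".",
            f"prophage_{i + 1}",
        )
        for i, (s, l) in enumerate(zip(DRI13_PROPHAGE_STARTS, DRI13_PROPHAGE_LENGTHS))
    ]

    truth = {
        "genome": gtruth,
        "annotation": atruth,
        "arrays": arrays,
        "cluster_gene_ids": cluster_ids,
        "methylome": mtruth,
        "depletion_region": (mb + 1, 2 * mb),
        "scale": scale,
        "seed": seed,
    }
    out = {
        "genome": genome,
        "genes": genes,
        "records": records,
        "arrays": arrays,
        "prophages": prophages,
        "model": model,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_gff3(genes, outdir / "genes.gff3", {genome.name: L})
        write_methylation_table(records, outdir / "meth.tsv")
        from .io import write_bed

        write_bed(
            [GenomicInterval(genome.name, *tr["region"], ".", f"array_{i + 1}") for i, tr in enumerate(arrays)],
            outdir / "arrays.bed",
        )
        write_bed(prophages, outdir / "prophages.bed")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=str)
    return out
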