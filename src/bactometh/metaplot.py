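"""Gene-anchored methylation metaplots and promoter K-means clustering.

Every gene body is rescaled onto a fixed number of body bins (100 by default,
a 1-kb-equivalent axis) with fixed-width flank bins on either side, oriented
5'->3' so that column 0 is always the far upstream end and the TSS sits at the
first body column. Averaging the matrix over genes gives the classic metagene
profile; clustering the promoter-window columns isolates gene groups with
distinctive promoter methylation (e.g. a small TSS-proximal mCpG-enriched
cluster against a background of TSS-depleted genes).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import GeneFeature

log = logging.getLogger(__name__)


@dataclass
class MetaplotMatrix:
    """Genes x positional-bins matrix of mean methylation fractions.

    Columns: ``flank_bins`` upstream, ``body_bins`` body, ``flank_bins``
    downstream; NaN where a gene/bin has no called site. Rows are oriented
    along each gene's own 5'->3' axis.
    """

    values: np.ndarray
    gene_ids: list[str]
    context: str
    flank: int
    body_bins: int
    flank_bins: int

    @property
    def n_columns(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    @property
    def tss_column(self) -> int:
        """0-based index of the first body column (the TSS anchor)."""
        return self.flank_bins

    @property
    def tts_column(self) -> int:
        """0-based index of the last body column (the TTS anchor)."""
        return self.flank_bins + self.body_bins - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids)


@dataclass
class ClusterResult:
    k: int
    assignment: dict  # gene id -> cluster id
    enriched_cluster_id: int
    enriched_members: list[str]
    cluster_promoter_means: dict  # cluster id -> mean promoter fraction


def gene_metaplot(
    records: pd.DataFrame,
    genes: list[GeneFeature],
    context: str,
    flank: int = 1000,
    body_bins: int = 100,
    flank_bins: int = 50,
    genome_length: int | None = None,
    circular: bool = True,
) -> MetaplotMatrix:
    """Build the per-gene positional methylation matrix for one context.

    ``context`` may be a plain context name (sites on either genomic strand
    are used) or the strand-specific ``"CHH_fwd"`` / ``"CHH_rev"``. A site
    falls in the body bin containing its position after rescaling the body to
    ``body_bins`` windows (1-based ceiling rule: offset o of a length-g body
    lands in bin ceil(o/g * body_bins)); flanks use fixed-width windows.
    Flanks may wrap the origin of a circular genome. Genes shorter than
    ``body_bins`` are skipped (counted in a logged warning).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ctx, strand = _parse_context(context)
    sub = records[records["context"] == ctx]
    if strand is not None:
        sub = sub[sub["strand"] == strand]
    positions = sub["position"].to_numpy(np.int64)
    fractions = sub["fraction"].to_numpy(float)

    if genome_length is None:
        genome_length = int(positions.max()) if len(positions) else max((g.end for g in genes), default=1)

    n_cols = 2 * flank_bins + body_bins
    flank_w = flank / flank_bins if flank_bins else 1.0
    kept_genes = [g for g in genes if g.length >= body_bins]
    n_skipped = len(genes) - len(kept_genes)
    if n_skipped:
        log.warning("skipped %d genes shorter than body_bins=%d", n_skipped, body_bins)

    sums = np.zeros((len(kept_genes), n_cols))
    counts = np.zeros((len(kept_genes), n_cols), dtype=np.int64)

    # per-position lookup: sites sorted once, genes query by interval
    order = np.argsort(positions)
    positions, fractions = positions[order], fractions[order]

    for gi, gene in enumerate(kept_genes):
        for pos, frac in _sites_near(positions, fractions, gene, flank, genome_length, circular):
            col = _column_of(pos, gene, flank, flank_w, body_bins, flank_bins, genome_length, circular)
            if col is not None:
                sums[gi, col] += frac
                counts[gi, col] += 1

    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetaplotMatrix(
        values=values,
        gene_ids=[g.feature_id for g in kept_genes],
        context=context,
        flank=flank,
        body_bins=body_bins,
        flank_bins=flank_bins,
    )


def _parse_context(context: str) -> tuple[str, str | None]:
    if context.endswith("_fwd"):
        return context[:-4], "+"
    if context.endswith("_rev"):
        return context[:-4], "-"
    return context, None


def _sites_near(positions, fractions, gene, flank, L, circular):
    """Yield (pos, fraction) for sites within gene +/- flank, wrapping if circular."""
    lo, hi = gene.start - flank, gene.end + flank
    if lo >= 1 and hi <= L:
        i, j = np.searchsorted(positions, (lo, hi + 1))
        yield from zip(positions[i:j].tolist(), fractions[i:j].tolist())
        return
    if not circular:
        lo, hi = max(lo, 1), min(hi, L)
        i, j = np.searchsorted(positions, (lo, hi + 1))
        yield from zip(positions[i:j].tolist(), fractions[i:j].tolist())
        return
    # wrapped interval: [lo mod L, L] U [1, hi mod L]
    for a, b in _split_circular(lo, hi, L):
        i, j = np.searchsorted(positions, (a, b + 1))
        yield from zip(positions[i:j].tolist(), fractions[i:j].tolist())


def _split_circular(lo: int, hi: int, L: int):
    """1-based inclusive sub-intervals of a possibly-wrapping interval."""
    if hi - lo + 1 >= L:
        return [(1, L)]
    lo_m = (lo - 1) % L + 1
    hi_m = (hi - 1) % L + 1
    if lo_m <= hi_m:
        return [(lo_m, hi_m)]
    return [(lo_m, L), (1, hi_m)]


def _column_of(pos, gene, flank, flank_w, body_bins, flank_bins, L, circular):
    """Matrix column (0-based) for a site at forward position ``pos``.

    Distances are measured along the gene's own orientation; for '-' genes
    upstream lies at larger forward coordinates.
    """
    if circular:
        # choose the representation of pos closest to the gene
        cands = [pos, pos - L, pos + L]
        pos = min(cands, key=lambda p: _dist_to_interval(p, gene.start, gene.end))
    if gene.strand == "+":
        if gene.start <= pos <= gene.end:
            off = pos - gene.start + 1
            return flank_bins + min(math.ceil(off / gene.length * body_bins), body_bins) - 1
        if pos < gene.start:  # upstream
            d = gene.start - pos
            if d > flank:
                return None
            return flank_bins - math.ceil(d / flank_w)
        d = pos - gene.end  # downstream
        if d > flank:
            return None
        return flank_bins + body_bins + math.ceil(d / flank_w) - 1
    else:
        if gene.start <= pos <= gene.end:
            off = gene.end - pos + 1
            return flank_bins + min(math.ceil(off / gene.length * body_bins), body_bins) - 1
        if pos > gene.end:  # upstream of a '-' gene
            d = pos - gene.end
            if d > flank:
                return None
            return flank_bins - math.ceil(d / flank_w)
        d = gene.start - pos
        if d > flank:
            return None
        return flank_bins + body_bins + math.ceil(d / flank_w) - 1


def _dist_to_interval(p, a, b):
    if p < a:
        return a - p
    if p > b:
        return p - b
    return 0


def aggregate_profile(matrix: MetaplotMatrix) -> pd.DataFrame:
    """Column means over genes, ignoring missing; with per-column n."""
    if matrix.values.size == 0:
        raise ValueError("empty metaplot matrix")
    n = np.sum(~np.isnan(matrix.values), axis=0)
    sums = np.nansum(matrix.values, axis=0)
    means = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"column": np.arange(matrix.n_columns), "mean_fraction": means, "n_genes": n})


def promoter_columns(
    matrix: MetaplotMatrix, upstream: int = 200, downstream: int = 50
) -> np.ndarray:
    """Column indices covering TSS-upstream..TSS+downstream.

    Upstream distance is resolved on the fixed flank-bin grid; the downstream
    extent is resolved on the 1-kb-equivalent body axis (body treated as
    ``flank`` bp for this purpose), so the window includes the -35 promoter
    element region and the first ~50 bp of the body.
    """
    flank_w = matrix.flank / matrix.flank_bins
    n_up = min(math.ceil(upstream / flank_w), matrix.flank_bins)
    body_w = matrix.flank / matrix.body_bins  # 1-kb-equivalent body bin width
    n_down = min(math.ceil(downstream / body_w), matrix.body_bins)
    return np.arange(matrix.tss_column - n_up, matrix.tss_column + n_down)


def cluster_promoters(
    matrix: MetaplotMatrix,
    k: int = 6,
    promoter_upstream: int = 200,
    promoter_downstream: int = 50,
    seed: int = 0,
    n_init: int = 50,
    pool: int = 5,
) -> ClusterResult:
    """K-means on the promoter-window columns; report the enriched cluster.

    Adjacent promoter columns are pooled in groups of ``pool`` (NaN-ignoring
    mean) before clustering: single metaplot bins cover only ~20 bp and often
    hold no called site, and a partition driven by which bins happen to be
    empty would track coverage, not methylation. Rows must have at least one
    non-missing promoter value; a still-missing pooled feature is imputed
    with the row's own mean of observed features, *for the clustering step
    only* (never fed back into a statistic) — zero-filling would again let
    coverage gaps, not methylation, drive the partition. The enriched
    cluster is the one maximising mean promoter methylation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if pool < 1:
        raise ValueError("pool must be >= 1")
    cols = promoter_columns(matrix, promoter_upstream, promoter_downstream)
    sub = matrix.values[:, cols]
    has_data = ~np.all(np.isnan(sub), axis=1)
    ids = [g for g, keep in zip(matrix.gene_ids, has_data) if keep]
    sub = sub[has_data]
    groups = [np.arange(i, min(i + pool, sub.shape[1])) for i in range(0, sub.shape[1], pool)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pooled cells
        pooled = np.column_stack([np.nanmean(sub[:, g], axis=1) for g in groups])
        row_mean = np.nanmean(pooled, axis=1)
    X = np.where(np.isnan(pooled), row_mean[:, None], pooled)
    if len(X) < k:
        raise ValueError(f"only {len(X)} usable rows for k={k}")
    # fit on a canonically ordered copy so membership is invariant to the
    # caller's row order, then assign the original rows
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    km.fit(X[np.lexsort(X.T[::-1])])
    labels = km.predict(X)
    means = {int(c): float(X[labels == c].mean()) for c in np.unique(labels)}
    enriched = max(means, key=means.get)
    assignment = {g: int(c) for g, c in zip(ids, labels)}
    members = [g for g, c in assignment.items() if c == enriched]
    return ClusterResult(
        k=k,
        assignment=assignment,
        enriched_cluster_id=enriched,
        enriched_members=members,
        cluster_promoter_means=means,
    )
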