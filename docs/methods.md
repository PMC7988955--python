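# Methods

## Coordinates, strands, records

All internal coordinates are 1-based inclusive on the forward strand of a
single (usually circular) chromosome; BED/bedGraph output converts to
0-based half-open at the boundary. A methylation record is one called site:
contig, position, strand, modified base (A or C), context, read coverage,
and the fraction of reads carrying the modification (∈ [0,1]). Records are
carried as a validated pandas DataFrame; adenine records always belong to
the Dam channel, cytosine records to CpG/CHG/CHH/Dcm. Origin-spanning
annotation features are rejected; sequence motifs, flanks and sliding
windows do wrap the origin of a circular genome.

## Context scanning

Dam is an occurrence of GATC, Dcm of CCAGG/CCTGG (CCWGG). Both motif sets
are self-complementary, so forward-strand occurrences enumerate both
strands: each duplex locus carries one scorable base per strand (the A of
GATC; the second C of each strand's own CCWGG reading). Remaining cytosines
get the trinucleotide label with precedence CpG > CHG > CHH (H = A/C/T);
cytosines inside a Dcm footprint are claimed by Dcm and never
double-labelled — every A and C yields at most one site per strand. Any
window containing N yields no site. The choice of precedence and the
claiming rule are this package's own; overlapping-label resolution is not
standardised in the field. The scanner is verified against a per-position
brute-force oracle and is rotation-invariant on circular genomes.

"Number of motifs" is reported two ways — per-strand site counts and
distinct duplex loci — because published tables are ambiguous between them
for palindromic contexts (a CG duplex is one locus but two scorable
cytosines).

## Per-context methylation level

For a context with called records *i = 1..N*,
`pct = 100 · Σ fᵢ / N` — an unweighted mean over sites, not reads: dividing
by the motif count rather than total coverage stops deep sites from
dominating. Records are first coverage-filtered, boundary inclusive;
defaults are 30× for CpG, Dcm and Dam and 1× for the de novo CHH/CHG
channels, reflecting how palindromic calls are typically hard-filtered
while de novo asymmetric calls arrive pre-thresholded. Coverage summaries
report both mean and median (published "context-specific coverage" values
do not state which; mean is the primary). Quartiles of per-site fractions
use linear interpolation. A context with zero called records raises rather
than reporting 0% — absence of evidence is not hypomethylation. Binned
profiles (default 100-kb non-overlapping bins, last bin partial and kept at
its true width) apply the same unweighted mean per bin, so the global
statistic equals the site-count-weighted mean of bin values; empty bins are
NaN, distinct from 0, because strand-specific depletion regions make that
distinction material.

## Metagene matrix and promoter clustering

Each gene body is rescaled onto 100 bins (a 1-kb-equivalent axis; genes
shorter than the bin count are skipped with a logged count) with 1-kb
flanks of 50 fixed 20-bp bins each side, rows oriented along the gene's own
5′→3′ axis. A site at body offset *o* of a length-*g* gene lands in bin
⌈o/g·100⌉; flank bins are fixed-width. Cell values are mean fractions of
called sites; cells without sites are NaN. Aggregating column means (NaN
ignored, per-column n reported) gives the metagene profile.

Promoter clustering runs K-means (Euclidean, k-means++, 50 restarts,
seeded) on the promoter-window columns, TSS−200…TSS+50 by default — wide
enough to include the −35 promoter element; the downstream extent is
resolved on the 1-kb-equivalent body axis. Two numerical choices matter on
per-site data and are deliberate:

* **Column pooling.** Adjacent promoter columns are pooled in groups of 5
  (~100 bp, NaN-ignoring mean) before clustering. Single 20-bp bins often
  contain no called CpG site (~40% empty at realistic CpG density), and a
  partition computed on sparse cells tracks which bins happen to be empty —
  coverage, not methylation.
* **Row-mean imputation.** A pooled feature still missing is imputed with
  the row's own mean of observed features, inside the clustering step only;
  no statistic elsewhere ever imputes. Zero-filling was tried and rejected
  for the same reason as unpooled columns: it lets coverage gaps drive the
  partition.

The fit runs on a canonically sorted copy of the feature matrix with labels
predicted for the original rows, so membership does not depend on caller row
order. The enriched cluster is the one maximising mean promoter
methylation. Default k = 6 echoes heatmap-style grouping and is exposed as
a flag; for recovering a single planted promoter-methylated cluster, k = 2
(background vs enriched) is the appropriate setting — at larger k, K-means
subdivides the enriched cloud along its own gradient and the argmax-mean
rule returns only its extreme slice. On dense per-gene matrices the
enriched cluster is recovered with ≥0.9 precision and recall (planted
Δ = 0.3, 20 of 1,000 genes); on full per-site simulations at the default
dispersion (κ = 5) recall at k = 2 is ~1.0 while precision settles near
0.7–0.8 because a few percent of background genes draw genuinely high
fractions over their handful of promoter sites — an overlap present in the
data itself, which no membership rule can undo.

## CRISPR arrays

`parse_array` scans a declared region for a ≥20-bp repeat consensus at every
offset in both orientations (Hamming distance ≤ 3 by default), keeps the
orientation with more repeats (ties: fewer mismatches), and accepts matches
greedily left-to-right without overlap, preferring the cleanest match in
each stretch. Gaps between consecutive repeats of 15–60 bp are spacers
(typical type-I geometry); oversized gaps are logged and never become
spacers. On a region bounded by repeats, spacers = repeats − 1.

The periodicity statistic is T = mean(spacer) − mean(repeat) over
strand-pooled element means, with a one-sided permutation p-value from
≥1,000 seeded shuffles of element labels; permutation is preferred to
spectral methods because element counts are small (tens). With the add-one
estimator, p cannot fall below 1/(n+1), so arrays with few elements cannot
reach very small p regardless of contrast. Elements without called sites
are excluded from T with a warning.

`map_spacers` slides every spacer over both strands of the circular genome
(vectorised Hamming at every offset, wrapping the origin; ≤2 mismatches by
default), removes hits inside the source array, and flags hits overlapping
prophage intervals. Mismatch defaults are this package's choices — the
analyses this mirrors used BLAST-style mapping without published
thresholds.

## Motif discovery

Foreground sites: one base, coverage ≥10, fraction ≥0.5 (defaults, exposed).
Each site contributes its ±4-bp window read 5′→3′ on its own strand; every
5-mer covering the modified base is counted by (k-mer, offset) pair.
Background: identical counts over *all* genomic positions of that base on
both strands, so base-composition bias cancels exactly — no shuffling
needed. Enrichment is `log2[(f+1)/(F+2) ÷ (b+1)/(B+2)]` (pseudocounted,
always finite); significance is a one-sided binomial at the background rate,
Bonferroni-corrected at 0.01 across all tested pairs. Because the
foreground is a large subsample of the background, the binomial is slightly
conservative under the null. Passing motifs are ranked by enrichment, and
motifs that are shifted views of the same context (all overlapping
characters agree when aligned at the modified base) collapse onto the
best-scoring representative. The procedure recovers planted G(A)ACT and
C(C)GG motifs and stays silent on uniform-random fractions; it replaces
signal-space detection entirely and makes no claim about signal-level
statistics.

## Genome structure

Strand-resolved gene counts use 1-Mb bins by gene start (midpoint optional;
boundary-spanning genes are not standardised in published tables), last bin
partial, with a totals row. GC content is (G+C)/(A+C+G+T) and skew
(G−C)/(G+C) per window (0 when G+C = 0; N excluded from denominators),
windows wrapping on circular genomes; tiling windows integrate exactly to
the whole-genome values. The strand-bias/methylation report computes
Spearman's ρ between per-bin reverse-strand gene counts and reverse-strand
mCHH (and the forward pair), methylation re-binned onto the gene grid by
site-count-weighted means, with a seeded permutation p-value. With only ~4
bins on a ~4-Mb chromosome the correlation is reported but underpowered; it
is a qualitative sign check, and fewer than 4 bins yields NaN.

## Synthetic data

The generator is the package's model of what the analysis assumes, not of
sequencing itself. Genomes are i.i.d. bases at a target GC (45% default);
motif planting substitutes (never inserts, so coordinates stay stable)
until the forward-occurrence count is within ±2% of target. Genes are
placed without overlap, lengths ~N(900, 250²) bp clipped at 150, intergenic
slack distributed multinomially, strand drawn per-bin from a bias vector
(the `dri13` preset uses forward proportions 0.695/0.173/0.392/0.818 per
scaled Mb, echoing a strongly reverse-biased second megabase). CRISPR
planting writes alternating repeat/spacer blocks (distinct random spacers)
and returns exact truth intervals.

Methylomes draw, per scanned context site, coverage ~ Poisson(λ_c) and
fraction ~ Beta(μ′κ, (1−μ′)κ). Defaults: μ = 0.764 (Dam), 0.0428 (CpG),
0.0381 (Dcm), 0.1741/0.1739 (CHH by strand), 0.10 (CHG); λ = 42/121/94/54
reads; κ = 5. Beta/Poisson is the simplest model producing a bounded
fraction with site-to-site dispersion and integer coverage; the true
site-level dispersion of real data is unpublished, so κ is a free parameter
(κ → ∞ collapses fractions onto their means). Modifiers: a reverse-strand
CHH multiplier (0.25) inside a depletion segment, a promoter mCpG boost
(+0.4 within TSS−200…TSS+50) for a designated gene cluster (45 genes at
preset scale), and spacer/repeat CHH means (0.4 / 0.02) inside planted
arrays. A separate generator emits per-base de novo calls for every A (or
C) on both strands, with motif-conditional means, for motif-discovery
studies. All generators are deterministic under a fixed seed and return
truth bundles.

What the generator does **not** emulate: read-level error and mapping bias,
coverage autocorrelation along the genome, motif co-occurrence structure,
operonic gene organisation, real intergenic length distributions, or
signal-level artefacts. Passing tests therefore show the *pipeline*
recovers the statistical structure it targets, not that any particular
biological dataset would behave identically.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale as the package's own
standard study sizes: 5,000 sites/context × 200 replicates for parameter
recovery; 1,000 genes with 20 planted (Δ = 0.3) × 50 seeds for cluster
recovery; 200 random 5-kb sequences for scanner/oracle agreement; a 200-kb
genome for planted-motif recovery and 100 × 50-kb genomes for the null
rate; a 19-repeat array for CRISPR checks; and a 5%-scale chromosome
(~190 kb, ~190 genes) for the end-to-end chain. Every stochastic step takes
an explicit seed; the acceptance script derives all of its seeds from
`--seed`.
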