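"""Per-context methylation percentages and a binned genome profile.

A synthetic methylome is generated at realistic per-context levels
(Dam ~76%, CpG ~4%, Dcm ~4%, CHH ~17%), coverage-filtered at 30x for the
palindromic contexts, and summarized: the methylation % of a context is the
unweighted mean of per-site modification fractions, x100.
"""

import bactometh as bm
from bactometh.simulate import MethylomeModel, simulate_genome, simulate_methylome

genome, _ = simulate_genome(length=200_000, gc=0.45, seed=7)
records, _ = simulate_methylome(genome, MethylomeModel(seed=7))
called = bm.filter_by_coverage(records)

summary = bm.summarize_contexts(called)
print(summary[["context", "n_motifs", "methylation_pct", "mean_coverage"]]
      .round(2).to_string(index=False))

bins = bm.bin_genome(called, len(genome), width=50_000)
dam_bins = bins[bins["context"] == "Dam"]
print("\nDam level per 50-kb bin (NaN would mean no called site, not 0%):")
print(dam_bins[["bin", "start", "end", "methylation_pct", "n_sites"]]
      .round(2).to_string(index=False))
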