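"""De novo discovery of an enriched methylated motif.

All GAACT adenines of a 200-kb genome are given high modification fractions;
the k-mer enrichment scan over highly modified adenines recovers G(A)ACT as
the top-ranked motif against the all-adenine genomic background.
"""

import bactometh as bm
from bactometh.simulate import simulate_denovo_calls, simulate_genome

genome, _ = simulate_genome(200_000, seed=21)
records = simulate_denovo_calls(genome, base="A", motif_means={"GAACT": (1, 0.8)},
                                background_mean=0.02, seed=22)
sites = bm.select_modified_sites(records, "A", min_fraction=0.5, min_cov=10)
print(f"{len(sites)} highly modified adenines selected as foreground")

motifs = bm.enrich_kmers(genome, sites, "A", k=5, flank=4)
for m in motifs[:3]:
    print(f"{m.consensus:12s} fg={m.foreground:5d} bg={m.background:6d} "
          f"log2 enrichment={m.log2_enrichment:5.2f} p_bonf={m.p_bonferroni:.2e}")
print("\nthe bracketed base is the modified one; enrichment compares the "
      "foreground k-mer rate with the genomic all-adenine background.")
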