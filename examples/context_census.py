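"""Scan a circular genome for methylation-context sites and print the census.

Dam (GATC) and Dcm (CCWGG) are palindromic: each duplex locus contributes one
scorable base per strand, so the site count is twice the locus count. CHH is
asymmetric, so its forward and reverse sites are independent.
"""

import bactometh as bm
from bactometh.simulate import simulate_genome

genome, _ = simulate_genome(length=100_000, gc=0.45, seed=1)
sites = bm.scan_contexts(genome)
print(bm.census(sites).as_frame().to_string(index=False))
print(f"\n{len(sites)} scorable sites on a {len(genome):,} bp genome; "
      "n_duplex_loci counts double-stranded motif occurrences once.")
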