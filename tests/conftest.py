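import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from bactometh.io import GenomeSequence


def random_genome(length: int, seed: int, gc: float = 0.45, circular: bool = True) -> GenomeSequence:
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return GenomeSequence("rand", seq, circular)


def make_records(rows) -> pd.DataFrame:
    """rows: (position, strand, base, context, coverage, fraction)."""
    return pd.DataFrame(
        [("chr1", *r) for r in rows],
        columns=["contig", "position", "strand", "base", "context", "coverage", "fraction"],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One desk-scale synthetic dataset shared by the slower tests."""
    from bactometh.simulate import simulate_dataset

    return simulate_dataset(seed=11, scale=0.05)
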