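import numpy as np
import pytest

import bactometh as bm
from bactometh.io import GenomeSequence, GenomicInterval
from bactometh.simulate import REPEAT_ARRAY1, plant_crispr, simulate_genome
from conftest import make_records, random_genome

REPEAT = REPEAT_ARRAY1  # 37 bp


def build_array_genome(n_repeats=3, spacer_len=30, seed=0, pad=500):
    """Genome with one constructed array; returns genome, region, truth intervals."""
    rng = np.random.default_rng(seed)
    spacers = ["".join(rng.choice(list("ACGT"), size=spacer_len)) for _ in range(n_repeats - 1)]
    parts, pos = [], pad + 1
    repeats_iv, spacers_iv = [], []
    for i in range(n_repeats):
        parts.append(REPEAT)
        repeats_iv.append((pos, pos + len(REPEAT) - 1))
        pos += len(REPEAT)
        if i < n_repeats - 1:
            parts.append(spacers[i])
            spacers_iv.append((pos, pos + spacer_len - 1))
            pos += spacer_len
    flankseq = "".join(rng.choice(list("ACGT"), size=pad))
    flank2 = "".join(rng.choice(list("ACGT"), size=pad))
    seq = flankseq + "".join(parts) + flank2
    g = GenomeSequence("chr1", seq, circular=True)
    region = GenomicInterval("chr1", pad + 1 - 20, pos + 20, ".", "array")
    return g, region, repeats_iv, spacers_iv


class TestParseArray:
    def test_exact_recovery_of_constructed_array(self):
        g, region, repeats_iv, spacers_iv = build_array_genome(3, 30)
        arr = bm.parse_array(g, region, REPEAT)
        assert arr.n_repeats == 3 and arr.n_spacers == 2
        assert [(r.start, r.end) for r in arr.repeats] == repeats_iv
        assert [(s.start, s.end) for s in arr.spacers] == spacers_iv
        assert arr.repeat_mismatches == [0, 0, 0]

    def test_mismatched_repeat_still_found(self):
        g, region, repeats_iv, _ = build_array_genome(3, 30, seed=1)
        seq = list(g.sequence)
        p = repeats_iv[1][0]  # mutate two bases of the middle repeat
        for off in (3, 11):
            seq[p - 1 + off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p - 1 + off]]
        g2 = GenomeSequence("chr1", "".join(seq), circular=True)
        arr = bm.parse_array(g2, region, REPEAT, max_mismatch=3)
        assert arr.n_repeats == 3
        assert arr.repeat_mismatches[1] == 2

    def test_reverse_orientation_array(self):
        g, region, _, _ = build_array_genome(4, 25, seed=2)
        rc = GenomeSequence("chr1", bm.revcomp(g.sequence), circular=True)
        L = len(g)
        rc_region = GenomicInterval("chr1", L - region.end + 1, L - region.start + 1, ".", "array")
        arr = bm.parse_array(rc, rc_region, REPEAT)
        assert arr.orientation == "-"
        assert arr.n_repeats == 4 and arr.n_spacers == 3

    def test_spacer_equals_repeat_minus_one(self):
        for n in (2, 5, 9):
            g, region, _, _ = build_array_genome(n, 37, seed=n)
            arr = bm.parse_array(g, region, REPEAT)
            assert arr.n_spacers == arr.n_repeats - 1

    def test_zero_occurrences_error(self):
        g = random_genome(2000, seed=3)
        with pytest.raises(ValueError, match="no repeat occurrence"):
            bm.parse_array(g, GenomicInterval("rand", 1, 2000), REPEAT)

    def test_region_exceeding_genome_rejected(self):
        g = random_genome(1000, seed=3)
        with pytest.raises(ValueError, match="region exceeds"):
            bm.parse_array(g, GenomicInterval("rand", 1, 5000), REPEAT)

    def test_short_consensus_rejected(self):
        g = random_genome(1000, seed=3)
        with pytest.raises(ValueError, match=">= 20"):
            bm.parse_array(g, GenomicInterval("rand", 1, 1000), "GATCGATC")

    def test_oversized_gap_dropped_with_warning(self, caplog):
        # two repeat pairs separated by a 200-bp gap: gap is not a spacer
        rng = np.random.default_rng(7)
        mk = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        seq = mk(100) + REPEAT + mk(30) + REPEAT + mk(200) + REPEAT + mk(30) + REPEAT + mk(100)
        g = GenomeSequence("chr1", seq, circular=False)
        with caplog.at_level("WARNING"):
            arr = bm.parse_array(g, GenomicInterval("chr1", 1, len(seq)), REPEAT)
        assert arr.n_repeats == 4
        assert arr.n_spacers == 2
        assert "split" in caplog.text

    def test_planted_array_roundtrip(self):
        genome, _ = simulate_genome(30_000, seed=5)
        genome, truth = plant_crispr(genome, REPEAT, n_repeats=19, spacer_len=37,
                                     location=10_000, seed=8)
        lo, hi = truth["region"]
        assert hi - lo + 1 == 19 * 37 + 18 * 37
        arr = bm.parse_array(genome, GenomicInterval(genome.name, lo, hi), REPEAT)
        assert [(r.start, r.end) for r in arr.repeats] == truth["repeats"]
        assert [(s.start, s.end) for s in arr.spacers] == truth["spacers"]


class TestMethylationProfile:
    def array_with_records(self, spacer_frac, repeat_frac, seed=0, n_repeats=6):
        g, region, repeats_iv, spacers_iv = build_array_genome(n_repeats, 30, seed=seed)
        arr = bm.parse_array(g, region, REPEAT)
        rows = []
        rng = np.random.default_rng(seed)
        for kind, ivs, frac in (("r", repeats_iv, repeat_frac), ("s", spacers_iv, spacer_frac)):
            for a, b in ivs:
                for p in range(a, b + 1, 3):
                    f = frac if not callable(frac) else frac(rng)
                    rows.append((p, "+" if p % 2 else "-", "C", "CHH", 40, f))
        return arr, make_records(rows)

    def test_extreme_contrast(self):
        arr, rec = self.array_with_records(1.0, 0.0, n_repeats=19)
        table, stat = bm.array_methylation_profile(arr, rec, seed=0)
        assert stat["T"] == pytest.approx(1.0)
        assert stat["p_value"] <= 0.001 + 1e-9

    def test_null_shuffled_fractions(self):
        hits = 0
        for seed in range(20):
            arr, rec = self.array_with_records(
                lambda r: r.uniform(), lambda r: r.uniform(), seed=seed, n_repeats=10
            )
            _, stat = bm.array_methylation_profile(arr, rec, seed=seed)
            if stat["p_value"] > 0.05:
                hits += 1
        assert hits >= 18  # >= 90% of null seeds non-significant

    def test_empty_repeats_warn_and_compute(self, caplog):
        g, region, repeats_iv, spacers_iv = build_array_genome(3, 30, seed=4)
        arr = bm.parse_array(g, region, REPEAT)
        rows = [(p, "+", "C", "CHH", 40, 0.5) for a, b in spacers_iv for p in range(a, b + 1, 5)]
        with caplog.at_level("WARNING"):
            table, stat = bm.array_methylation_profile(arr, make_records(rows), seed=0)
        assert "excluded" in caplog.text
        assert np.isnan(stat["T"])  # no repeat element left to contrast

    def test_zero_spacer_array_rejected(self):
        g, region, _, _ = build_array_genome(2, 30, seed=5)
        arr = bm.parse_array(g, region, REPEAT)
        arr.spacers.clear()
        with pytest.raises(ValueError, match="no spacers"):
            bm.array_methylation_profile(arr, make_records([]))


class TestMapSpacers:
    def test_planted_prophage_hit(self):
        g, region, _, spacers_iv = build_array_genome(3, 30, seed=6, pad=2000)
        arr = bm.parse_array(g, region, REPEAT)
        sp = arr.spacer_sequences(g)[0]
        # copy spacer 1 into a "prophage" interval far from the array
        seq = g.sequence[:99] + sp + g.sequence[99 + len(sp):]
        g2 = GenomeSequence("chr1", seq, circular=True)
        prophage = GenomicInterval("chr1", 50, 400, ".", "prophage_1")
        hits = bm.map_spacers(arr, g2, [prophage], max_mismatch=0)
        assert len(hits) == 1
        h = hits[0]
        assert h.spacer_index == 1 and h.in_prophage and h.target.start == 100

    def test_random_spacers_no_hits(self):
        g, region, _, _ = build_array_genome(4, 35, seed=7, pad=5000)
        arr = bm.parse_array(g, region, REPEAT)
        hits = bm.map_spacers(arr, g, [], max_mismatch=0)
        assert hits == []

    def test_rotation_invariance(self):
        g, region, _, _ = build_array_genome(3, 30, seed=8, pad=1000)
        arr = bm.parse_array(g, region, REPEAT)
        sp = arr.spacer_sequences(g)[1]
        seq = g.sequence[:49] + sp + g.sequence[49 + len(sp):]
        g2 = GenomeSequence("chr1", seq, circular=True)
        base_hits = bm.map_spacers(arr, g2, [], max_mismatch=0)
        off = 333
        rot = GenomeSequence("chr1", g2.sequence[off:] + g2.sequence[:off], circular=True)
        L = len(g2)
        shift = lambda p: (p - 1 - off) % L + 1
        rot_region = GenomicInterval("chr1", shift(region.start), shift(region.end))
        rot_arr = bm.parse_array(rot, rot_region, REPEAT)
        rot_hits = bm.map_spacers(rot_arr, rot, [], max_mismatch=0)
        assert len(rot_hits) == len(base_hits) == 1
        assert shift(base_hits[0].target.start) == rot_hits[0].target.start

    def test_empty_spacer_list_rejected(self):
        g, region, _, _ = build_array_genome(2, 30, seed=9)
        arr = bm.parse_array(g, region, REPEAT)
        arr.spacers.clear()
        with pytest.raises(ValueError, match="no spacers"):
            bm.map_spacers(arr, g)
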