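import numpy as np
import pytest

import bactometh as bm
from bactometh.io import GeneFeature
from bactometh.simulate import simulate_promoter_matrix
from conftest import make_records


def gene(start, end, strand="+", fid="g1"):
    return GeneFeature("chr1", start, end, strand, fid)


class TestPlacement:
    def test_body_bin_ceiling_rule(self):
        rec = make_records([(1500, "+", "C", "CpG", 50, 0.8)])
        mat = bm.gene_metaplot(rec, [gene(1001, 2000)], "CpG", genome_length=10_000)
        col = mat.flank_bins + 50 - 1  # 1-based body column 50
        assert mat.values[0, col] == pytest.approx(0.8)
        assert np.isnan(np.delete(mat.values[0], col)).all()

    def test_reverse_strand_gene_is_mirrored(self):
        rec = make_records([(1500, "+", "C", "CpG", 50, 0.8)])
        mat = bm.gene_metaplot(rec, [gene(1001, 2000, "-")], "CpG", genome_length=10_000)
        col = mat.flank_bins + 51 - 1  # mirrored into body column 51
        assert mat.values[0, col] == pytest.approx(0.8)

    def test_no_records_all_missing_dimensions_kept(self):
        rec = make_records([]).astype({"position": int, "coverage": int, "fraction": float})
        mat = bm.gene_metaplot(rec, [gene(1001, 2000)], "CpG", genome_length=10_000)
        assert mat.values.shape == (1, 200)
        assert np.isnan(mat.values).all()

    def test_upstream_flank_orientation(self):
        # site 100 bp upstream of a '+' TSS lands in the last flank columns
        rec = make_records([(901, "+", "C", "CpG", 50, 0.6)])
        mat = bm.gene_metaplot(rec, [gene(1001, 2000)], "CpG", genome_length=10_000)
        d = 1001 - 901  # 100 bp -> flank bin ceil(100/20)=5 from TSS
        col = mat.flank_bins - 5
        assert mat.values[0, col] == pytest.approx(0.6)
        # same distance upstream of the equivalent '-' gene (upstream = right)
        rec2 = make_records([(2100, "+", "C", "CpG", 50, 0.6)])
        mat2 = bm.gene_metaplot(rec2, [gene(1001, 2000, "-")], "CpG", genome_length=10_000)
        assert mat2.values[0, col] == pytest.approx(0.6)

    def test_flank_wraps_circular_origin(self):
        rec = make_records([(9950, "+", "C", "CpG", 50, 0.4)])
        mat = bm.gene_metaplot(rec, [gene(30, 1030)], "CpG", genome_length=10_000, circular=True)
        assert np.nansum(mat.values) == pytest.approx(0.4)
        lin = bm.gene_metaplot(rec, [gene(30, 1030)], "CpG", genome_length=10_000, circular=False)
        assert np.isnan(lin.values).all()

    def test_short_genes_skipped(self):
        rec = make_records([(50, "+", "C", "CpG", 50, 0.5)])
        mat = bm.gene_metaplot(rec, [gene(10, 60, fid="tiny"), gene(1001, 2000, fid="ok")], "CpG",
                               genome_length=10_000)
        assert mat.gene_ids == ["ok"]

    def test_strand_specific_context_filter(self):
        rec = make_records(
            [(1500, "+", "C", "CHH", 50, 0.9), (1600, "-", "C", "CHH", 50, 0.1)]
        )
        fwd = bm.gene_metaplot(rec, [gene(1001, 2000)], "CHH_fwd", genome_length=10_000)
        assert np.nansum(fwd.values) == pytest.approx(0.9)
        rev = bm.gene_metaplot(rec, [gene(1001, 2000)], "CHH_rev", genome_length=10_000)
        assert np.nansum(rev.values) == pytest.approx(0.1)


class TestAggregate:
    def test_column_mean_over_genes(self):
        rec = make_records(
            [(1500, "+", "C", "CpG", 50, 0.2), (11500, "+", "C", "CpG", 50, 0.4)]
        )
        genes = [gene(1001, 2000, fid="a"), gene(11001, 12000, fid="b")]
        prof = bm.aggregate_profile(bm.gene_metaplot(rec, genes, "CpG", genome_length=20_000))
        col = 50 + 50 - 1
        row = prof.iloc[col]
        assert row["mean_fraction"] == pytest.approx(0.3)
        assert row["n_genes"] == 2

    def test_all_missing_column_stays_missing(self):
        rec = make_records([(1500, "+", "C", "CpG", 50, 0.2)])
        prof = bm.aggregate_profile(bm.gene_metaplot(rec, [gene(1001, 2000)], "CpG", genome_length=10_000))
        assert np.isnan(prof.iloc[0]["mean_fraction"])

    def test_single_gene_profile_equals_row(self):
        rec = make_records([(1500, "+", "C", "CpG", 50, 0.7)])
        mat = bm.gene_metaplot(rec, [gene(1001, 2000)], "CpG", genome_length=10_000)
        prof = bm.aggregate_profile(mat)
        np.testing.assert_array_equal(
            prof["mean_fraction"].to_numpy(), mat.values[0]
        )


def test_boundary_depletion_minima_near_tss_tts():
    """Flank-suppressed synthetic data reproduces TSS/TTS methylation dips."""
    rng = np.random.default_rng(42)
    genes = [gene(i * 5000 + 1001, i * 5000 + 3000, fid=f"g{i}") for i in range(40)]
    rows = []
    for g in genes:
        for p in range(g.start - 1000, g.end + 1001, 17):
            d = min(abs(p - g.start), abs(p - g.end))
            mu = 0.05 if d < 150 else 0.5  # suppressed near both boundaries
            rows.append((p, "+", "C", "CpG", 50, float(np.clip(rng.normal(mu, 0.05), 0, 1))))
    rec = make_records(rows)
    mat = bm.gene_metaplot(rec, genes, "CpG", genome_length=300_000)
    prof = bm.aggregate_profile(mat)["mean_fraction"].to_numpy()
    tss, tts = mat.tss_column, mat.tts_column
    near_tss = np.nanargmin(prof[: (tss + tts) // 2])
    near_tts = (tss + tts) // 2 + np.nanargmin(prof[(tss + tts) // 2 :])
    assert abs(near_tss - tss) <= 5
    assert abs(near_tts - tts) <= 5


class TestCluster:
    def make_matrix(self, seed=0, n=100, planted=20, delta=0.5):
        return simulate_promoter_matrix(
            n_genes=n, n_planted=planted, delta=delta, base_mean=0.02, seed=seed
        )

    def test_planted_cluster_recovered(self):
        mat, planted = self.make_matrix()
        res = bm.cluster_promoters(mat, k=2, seed=1)
        assert len(set(res.enriched_members) & set(planted)) >= 19

    def test_identical_rows_degenerate(self):
        mat, _ = self.make_matrix(n=20, planted=0, delta=0)
        mat.values[:] = 0.3
        res = bm.cluster_promoters(mat, k=2, seed=0)
        counts = {}
        for c in res.assignment.values():
            counts[c] = counts.get(c, 0) + 1
        # all mass in one effective cluster; it is the enriched one
        assert counts[max(counts, key=counts.get)] >= 19
        assert res.enriched_cluster_id in counts

    def test_row_permutation_invariance(self):
        mat, _ = self.make_matrix(seed=3)
        res1 = bm.cluster_promoters(mat, k=3, seed=5)
        perm = np.random.default_rng(0).permutation(len(mat.gene_ids))
        mat2 = bm.MetaplotMatrix(
            mat.values[perm], [mat.gene_ids[i] for i in perm],
            mat.context, mat.flank, mat.body_bins, mat.flank_bins,
        )
        res2 = bm.cluster_promoters(mat2, k=3, seed=5)
        assert set(res1.enriched_members) == set(res2.enriched_members)

    def test_k_validation(self):
        mat, _ = self.make_matrix(n=10, planted=2)
        with pytest.raises(ValueError):
            bm.cluster_promoters(mat, k=1)
        with pytest.raises(ValueError):
            bm.cluster_promoters(mat, k=50)

    def test_enriched_cluster_maximises_promoter_mean(self):
        mat, _ = self.make_matrix(seed=7)
        res = bm.cluster_promoters(mat, k=4, seed=2)
        assert res.cluster_promoter_means[res.enriched_cluster_id] == max(
            res.cluster_promoter_means.values()
        )


def test_promoter_columns_cover_minus35():
    mat, _ = simulate_promoter_matrix(n_genes=5, n_planted=0, seed=0)
    cols = bm.promoter_columns(mat)
    flank_w = mat.flank / mat.flank_bins
    # the -35 element lies 35 bp upstream: flank bin ceil(35/20)=2 before TSS
    assert mat.tss_column - 2 in cols
    assert cols.min() == mat.tss_column - 10 and cols.max() == mat.tss_column + 4
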