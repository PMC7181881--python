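"""Expression pipeline: QC, normalization, PCs, clustering, markers, DE."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from neurogi import sc, synthetic
from neurogi.synthetic import SimConfig


def make_adata(X, mito_flags=None, lengths=None):
    X = np.asarray(X)
    n, g = X.shape
    var = pd.DataFrame(
        {
            "length": lengths if lengths is not None else np.full(g, 10_000.0),
            "mito": mito_flags if mito_flags is not None else np.zeros(g, bool),
        },
        index=[f"g{j}" for j in range(g)],
    )
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


class TestQcFilter:
    def test_cell_below_gene_floor_removed(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(5, 400))
        X[X == 0] = 1                      # everyone detects 400 genes
        X[0, 299:] = 0                     # cell 0 detects exactly 299
        a = sc.qc_filter(make_adata(X), min_genes=300, min_cells=1)
        assert "c0" not in a.obs_names
        assert a.n_obs == 4

    def test_clean_matrix_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, size=(6, 350)) + 1
        a0 = make_adata(X)
        a = sc.qc_filter(a0)
        assert a.shape == a0.shape
        assert np.array_equal(np.asarray(a.X), X)

    def test_mito_fraction_filter(self):
        X = np.ones((4, 400), dtype=int)
        mito = np.zeros(400, bool)
        mito[:20] = True  # baseline mito fraction 20/400 = 5%
        X[0, :20] = 30    # cell 0: 600 mito / 980 total > 10%
        a = sc.qc_filter(make_adata(X, mito_flags=mito), min_cells=1)
        assert "c0" not in a.obs_names

    def test_survivors_match_brute_force_recount(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(1.2, size=(30, 500))
        mito = np.zeros(500, bool)
        mito[:10] = True
        a = sc.qc_filter(make_adata(X, mito_flags=mito),
                         min_genes=150, max_mito_frac=0.05, min_cells=3)
        # independent recount
        keep_cells = []
        for i in range(30):
            det = sum(1 for v in X[i] if v > 0)
            mfrac = X[i, :10].sum() / max(X[i].sum(), 1)
            if det >= 150 and mfrac <= 0.05:
                keep_cells.append(i)
        assert list(a.obs_names) == [f"c{i}" for i in keep_cells]
        sub = X[keep_cells]
        keep_genes = [j for j in range(500)
                      if sum(1 for v in sub[:, j] if v > 0) >= 3]
        assert list(a.var_names) == [f"g{j}" for j in keep_genes]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(0.8, size=(40, 600))
        a1 = sc.qc_filter(make_adata(X), min_genes=100)
        a2 = sc.qc_filter(a1, min_genes=100)
        assert a1.shape == a2.shape
        assert np.array_equal(np.asarray(a1.X), np.asarray(a2.X))

    def test_all_filtered_raises(self):
        X = np.ones((3, 10), dtype=int)
        with pytest.raises(ValueError, match="all cells"):
            sc.qc_filter(make_adata(X), min_genes=300)


class TestNormalize:
    def test_equal_totals_scale_factor_one(self):
        X = np.tile(np.arange(1, 6), (3, 1))
        a = sc.normalize(make_adata(X))
        np.testing.assert_allclose(np.asarray(a.X), np.log1p(X))

    def test_two_cell_toy_hand_arithmetic(self):
        # totals 100 and 300, median 200 -> factors 2.0 and 2/3
        X = np.array([[100, 0], [150, 150]])
        a = sc.normalize(make_adata(X))
        out = np.asarray(a.X)
        assert out[0, 0] == pytest.approx(np.log1p(200.0))
        assert out[1, 0] == pytest.approx(np.log1p(100.0))
        assert out[0, 1] == 0.0  # zero maps to zero

    def test_preserves_zero_pattern_and_rank_order(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(1.0, size=(10, 50))
        a = sc.normalize(make_adata(X))
        out = np.asarray(a.X)
        assert ((out == 0) == (X == 0)).all()
        for i in range(10):
            assert (sps.rankdata(out[i]) == sps.rankdata(X[i])).all()

    def test_zero_total_cell_errors(self):
        X = np.vstack([np.ones(5, int), np.zeros(5, int)])
        with pytest.raises(ValueError, match="zero total"):
            sc.normalize(make_adata(X))


class TestSelectPcs:
    def test_iid_noise_retains_almost_nothing(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((150, 80))
        out = sc.select_pcs(X, n_perm=100, seed=0)
        assert out["n_pcs"] <= 2

    def test_planted_rank_five_recovered(self):
        rng = np.random.default_rng(6)
        U = rng.standard_normal((200, 5))
        V = rng.standard_normal((5, 100)) * 3.0
        X = U @ V + rng.standard_normal((200, 100))
        out = sc.select_pcs(X, n_perm=100, seed=0)
        assert out["n_pcs"] == 5

    def test_metadata_recorded(self):
        X = np.random.default_rng(7).standard_normal((30, 20))
        out = sc.select_pcs(X, n_perm=10, quantile=0.95, seed=3)
        assert out["n_perm"] == 10 and out["seed"] == 3

    def test_nperm_validation(self):
        with pytest.raises(ValueError):
            sc.select_pcs(np.eye(5), n_perm=0)


class TestCluster:
    @staticmethod
    def _blob_adata(seed=0, sep=12.0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(c, 1.0, size=(50, 20))
                         for c in (0.0, sep, 2 * sep)])
        return make_adata(np.abs(pts * 10).astype(int))

    def test_three_blobs_recovered(self):
        a = self._blob_adata()
        res = sc.cluster(a, n_pcs=5, k_grid=(10, 20), seed=0)
        assert res.labels.nunique() == 3
        assert res.silhouette > 0.8

    def test_identical_points_single_cluster(self):
        a = make_adata(np.ones((30, 10), dtype=int))
        res = sc.cluster(a, n_pcs=2, k_grid=(5,), seed=0)
        assert res.labels.nunique() == 1

    def test_k_at_least_n_cells_errors(self):
        a = self._blob_adata()
        with pytest.raises(ValueError):
            sc.cluster(a, n_pcs=5, k_grid=(500,), seed=0)

    def test_synthetic_classes_recovered(self, small_sc_adata):
        from sklearn.metrics import adjusted_rand_score

        a = sc.normalize(sc.qc_filter(small_sc_adata))
        res = sc.cluster(a, n_pcs=10, k_grid=(15, 30), seed=0)
        ari = adjusted_rand_score(a.obs["cell_class"], res.labels)
        assert ari > 0.9


class TestMarkerGenes:
    @staticmethod
    def _adata_with_marker():
        rng = np.random.default_rng(8)
        X = rng.poisson(1.0, size=(200, 30))
        X[:50, 0] = rng.poisson(8.0, size=50) + 1   # cluster 0 marker
        X[50:, 0] = 0
        labels = pd.Series([0] * 50 + [1] * 150,
                           index=[f"c{i}" for i in range(200)])
        return make_adata(X), labels

    def test_clean_marker_flagged_with_tiny_p(self):
        a, labels = self._adata_with_marker()
        mk = sc.marker_genes(a, labels)
        row = mk[(mk["cluster"] == 0) & (mk["gene"] == "g0")]
        assert len(row) == 1
        assert row["p"].iloc[0] < 1e-10

    def test_equal_rates_not_flagged(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(2.0, size=(100, 20))
        labels = pd.Series([0] * 50 + [1] * 50,
                           index=[f"c{i}" for i in range(100)])
        mk = sc.marker_genes(make_adata(X), labels)
        assert len(mk) <= 2  # chance flags only

    def test_p_matches_binomial_tail_closed_form(self):
        a, labels = self._adata_with_marker()
        mk = sc.marker_genes(a, labels)
        row = mk[(mk["cluster"] == 0) & (mk["gene"] == "g0")].iloc[0]
        expected = sps.binom.sf(row["detected_in"] - 1, row["n_in"],
                                row["rate_out"])
        assert row["p"] == pytest.approx(expected)

    def test_canonical_markers_assigned_to_their_class(self, small_sc_adata):
        a = sc.normalize(sc.qc_filter(small_sc_adata))
        res = sc.cluster(a, n_pcs=10, k_grid=(15,), seed=0)
        mk = sc.marker_genes(a, res.labels)
        # map clusters to majority class, then check marker placement
        majority = {
            cl: a.obs["cell_class"][res.labels == cl].mode()[0]
            for cl in res.labels.unique()
        }
        for cls, gene in synthetic.MARKER_GENES.items():
            hit = mk[mk["gene"] == gene]
            assert len(hit) >= 1
            assert majority[hit.iloc[0]["cluster"]] == cls

    def test_single_cluster_errors(self):
        a, _ = self._adata_with_marker()
        labels = pd.Series(0, index=a.obs_names)
        with pytest.raises(ValueError):
            sc.marker_genes(a, labels)


class TestDifferentialExpression:
    def test_planted_fourfold_reduction_recovered(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_cells_per_class=200, n_genes=400,
                            length_effect_beta=0.0)
            a = synthetic.generate_sc_dataset(cfg)
            exc = a[a.obs["cell_class"] == "excitatory"]
            de = sc.differential_expression(exc)
            if de.table.loc["Top1", "p_adj"] < 0.05:
                hits += 1
        assert hits >= 9

    def test_sign_matches_truth_for_large_effects(self):
        cfg = SimConfig(seed=3, n_cells_per_class=200, length_effect_beta=1.0)
        a = synthetic.generate_sc_dataset(cfg)
        exc = a[a.obs["cell_class"] == "excitatory"]
        de = sc.differential_expression(exc)
        truth = a.var["truth_log2fc"]
        big = truth[truth <= -1.0].index.intersection(de.table.index)
        big = big[de.table.loc[big, "mu_wt"] >= 0.5]  # detectably expressed
        assert len(big) > 10
        assert (de.table.loc[big, "log2fc"] < 0).all()

    def test_all_zero_genes_excluded_and_recorded(self):
        rng = np.random.default_rng(10)
        X = rng.poisson(1.0, size=(40, 10))
        X[:, 3] = 0
        a = make_adata(X)
        a.obs["genotype"] = ["WT"] * 20 + ["cKO"] * 20
        de = sc.differential_expression(a)
        assert "g3" in de.excluded
        assert "g3" not in de.table.index

    def test_adjusted_p_at_least_raw(self):
        cfg = SimConfig(seed=4, n_cells_per_class=50)
        a = synthetic.generate_sc_dataset(cfg)
        de = sc.differential_expression(a[a.obs["cell_class"] == "glia"])
        assert (de.table["p_adj"] >= de.table["p"] - 1e-12).all()

    def test_bh_fdr_controlled_under_global_null(self):
        # with no true effects any BH discovery is false; the realized FDR
        # over seeds must stay near the nominal level
        fdr = []
        for seed in range(20):
            cfg = SimConfig(seed=100 + seed, n_cells_per_class=60,
                            n_genes=300, length_effect_beta=0.0,
                            top1_log2fc=0.0)
            a = synthetic.generate_sc_dataset(cfg)
            de = sc.differential_expression(
                a[a.obs["cell_class"] == "excitatory"])
            R = (de.table["p_adj"] < 0.05).sum()
            fdr.append(1.0 if R > 0 else 0.0)
        assert np.mean(fdr) <= 0.10


class TestLengthBinCurve:
    @staticmethod
    def _de_from_values(log2fc, lengths):
        tbl = pd.DataFrame(
            {"log2fc": log2fc, "p": 0.5, "p_adj": 0.5},
            index=[f"g{j}" for j in range(len(log2fc))],
        )
        annot = pd.DataFrame({"length": lengths},
                             index=[f"g{j}" for j in range(len(log2fc))])
        return sc.DEResult(table=tbl), annot

    def test_zero_fold_changes_give_zero_bins(self):
        de, annot = self._de_from_values(np.zeros(450),
                                         np.linspace(1e3, 1e6, 450))
        curve = sc.length_bin_curve(de, annot, bin_size=200)
        assert (curve["mean_log2fc"] == 0).all()

    def test_401_genes_bin_sizes(self):
        de, annot = self._de_from_values(np.zeros(401),
                                         np.linspace(1e3, 1e6, 401))
        curve = sc.length_bin_curve(de, annot, bin_size=200)
        assert list(curve["n_genes"]) == [200, 200, 1]

    def test_counts_sum_and_ordering(self):
        rng = np.random.default_rng(11)
        de, annot = self._de_from_values(rng.normal(size=777),
                                         rng.uniform(1e3, 2e6, 777))
        curve = sc.length_bin_curve(de, annot, bin_size=200)
        assert curve["n_genes"].sum() == 777
        assert curve["mean_length"].is_monotonic_increasing

    def test_missing_length_errors(self):
        de, annot = self._de_from_values(np.zeros(10),
                                         np.linspace(1e3, 1e5, 10))
        with pytest.raises(ValueError):
            sc.length_bin_curve(de, annot.iloc[:5], bin_size=5)


class TestLongGeneSummary:
    def test_no_significant_genes_flagged_nan(self):
        tbl = pd.DataFrame({"log2fc": [0.1, -0.2], "p": [0.9, 0.8],
                            "p_adj": [0.9, 0.9]}, index=["g0", "g1"])
        annot = pd.DataFrame({"length": [1e4, 1e5]}, index=["g0", "g1"])
        md, ma, ratio = sc.long_gene_summary(sc.DEResult(table=tbl), annot)
        assert np.isnan(ratio)

    def test_matches_independent_mean(self):
        rng = np.random.default_rng(12)
        n = 200
        tbl = pd.DataFrame(
            {"log2fc": rng.normal(size=n), "p": rng.uniform(size=n)},
            index=[f"g{j}" for j in range(n)],
        )
        tbl["p_adj"] = tbl["p"]
        annot = pd.DataFrame({"length": rng.uniform(1e3, 1e6, n)},
                             index=tbl.index)
        md, ma, ratio = sc.long_gene_summary(sc.DEResult(table=tbl), annot)
        down = tbl[(tbl["p_adj"] < 0.05) & (tbl["log2fc"] < 0)].index
        assert md == pytest.approx(float(np.mean([annot.loc[g, "length"]
                                                  for g in down])))
        assert ma == pytest.approx(float(annot["length"].mean()))
        assert ratio == pytest.approx(md / ma)
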