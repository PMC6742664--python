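"""Single-cell pipeline rules: gates, normalization, HVG, PCA, clustering,
markers, noise-model ranking and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats
from sklearn.metrics import adjusted_rand_score

from fitsel import sc_pipeline as sc
from fitsel import synthetic_data as syn


def toy_matrix(counts: np.ndarray, genes: list[str],
               cell_meta: dict | None = None) -> syn.CountMatrix:
    n_cells = counts.shape[1]
    cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n_cells)]})
    for k, v in (cell_meta or {}).items():
        cells[k] = v
    return syn.CountMatrix(X=sparse.csr_matrix(counts.astype(np.int64)),
                           genes=pd.DataFrame({"gene": genes}),
                           cells=cells)


class TestQcFilter:
    def params(self, **kw):
        defaults = dict(min_genes_per_cell=3)
        defaults.update(kw)
        return sc.ScParams(**defaults)

    def test_all_pass_unchanged(self):
        counts = np.array([[9, 8, 7], [5, 5, 5], [1, 2, 3], [4, 4, 4]])
        cm = toy_matrix(counts, ["Pou4f1", "g1", "g2", "g3"])
        out = sc.qc_filter(cm, self.params())
        assert out.X.shape == cm.X.shape

    def test_toy_matrix_matches_brute_force(self):
        # 6 cells: 2 low-complexity, 1 gate-negative -> 3 survivors
        genes = ["Pou4f1", "g1", "g2", "g3", "g4"]
        counts = np.array([
            #  A   B   C   D   E   F
            [10,  9,  8,  2, 12,  7],   # Pou4f1 (D fails the > 5 gate)
            [ 3,  4,  5,  6,  0,  1],
            [ 2,  1,  3,  4,  0,  0],
            [ 1,  2,  0,  5,  0,  2],
            [ 4,  0,  1,  3,  0,  0],   # E, F low complexity
        ])
        cm = toy_matrix(counts, genes)
        p = self.params(min_genes_per_cell=4)
        out = sc.qc_filter(cm, p)
        survivors = []
        for j in range(6):
            if counts[0, j] > 5 and (counts[:, j] > 0).sum() >= 4:
                survivors.append(f"c{j}")
        assert out.cells["cell_id"].tolist() == survivors
        assert survivors == ["c0", "c1", "c2"]

    def test_gene_kept_at_exactly_three_cells(self):
        genes = ["Pou4f1", "in3", "in2", "pad1", "pad2"]
        counts = np.array([
            [9, 9, 9, 9],
            [1, 1, 1, 0],    # expressed in exactly 3 survivors -> kept
            [1, 1, 0, 0],    # in 2 -> removed
            [2, 2, 2, 2],
            [3, 3, 3, 3],
        ])
        out = sc.qc_filter(toy_matrix(counts, genes), self.params())
        assert "in3" in out.genes["gene"].tolist()
        assert "in2" not in out.genes["gene"].tolist()

    def test_missing_gate_gene_rejected(self):
        cm = toy_matrix(np.ones((2, 2), dtype=int), ["g1", "g2"])
        with pytest.raises(KeyError):
            sc.qc_filter(cm, self.params())

    def test_default_matrix_keeps_exactly_sensory_cells(self, default_counts):
        out = sc.qc_filter(default_counts)
        kept = set(out.cells["truth_cluster"])
        assert kept == {"cluster1", "cluster2"}
        expect = default_counts.cells["truth_cluster"].isin(kept).sum()
        assert out.n_cells == expect


class TestVelocityPrefilter:
    def test_empty_matrix_stays_empty(self):
        cm = toy_matrix(np.zeros((3, 0), dtype=int), ["a", "b", "c"])
        out = sc.velocity_prefilter(cm)
        assert out.X.shape[1] == 0

    def test_gene_concentration_rule_boundary(self):
        p = sc.ScParams(min_total_reads=0, gene_total_min=38,
                        gene_single_cell_min=18)
        genes = ["conc", "spread"]
        counts = np.array([
            [20, 20, 0, 0],     # total 40, 20 in one cell -> kept
            [10, 10, 10, 10],   # total 40, max 10 -> removed
        ])
        out = sc.velocity_prefilter(toy_matrix(counts, genes), p)
        assert out.genes["gene"].tolist() == ["conc"]

    def test_random_toy_matrix_matches_double_loop_oracle(self, rng):
        p = sc.ScParams(min_total_reads=30, gene_total_min=25,
                        gene_single_cell_min=10, hemoglobin_share_max=1.0)
        counts = rng.integers(0, 12, size=(15, 10))
        cm = toy_matrix(counts, [f"g{i}" for i in range(15)])
        out = sc.velocity_prefilter(cm, p)
        keep_cells = [j for j in range(10) if counts[:, j].sum() >= 30]
        sub = counts[:, keep_cells]
        keep_genes = [i for i in range(15)
                      if sub[i].sum() >= 25 and (sub[i] >= 10).any()]
        assert out.X.shape == (len(keep_genes), len(keep_cells))
        assert out.genes["gene"].tolist() == [f"g{i}" for i in keep_genes]

    def test_rbc_cells_removed(self, default_counts):
        out = sc.velocity_prefilter(default_counts)
        assert "rbc" not in set(out.cells["truth_cluster"])
        assert "low_quality" not in set(out.cells["truth_cluster"])


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self):
        counts = np.array([[0, 5], [10, 5]])
        norm = sc.log_normalize(toy_matrix(counts, ["a", "b"]))
        assert norm[0, 0] == 0.0

    def test_closed_form_value(self):
        # x = 10 in a cell of 10,000 total: ln(1 + 10) = 2.3979
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 10
        counts[1, 0] = 9990
        norm = sc.log_normalize(toy_matrix(counts, ["a", "b"]))
        assert norm[0, 0] == pytest.approx(np.log(11.0), abs=1e-6)

    def test_depth_invariance_of_scaled_values(self, rng):
        counts = rng.integers(0, 20, size=(30, 4))
        counts[0] += 1
        cm1 = toy_matrix(counts, [f"g{i}" for i in range(30)])
        cm2 = toy_matrix(counts * 3, [f"g{i}" for i in range(30)])
        assert np.allclose(sc.log_normalize(cm1), sc.log_normalize(cm2))

    def test_zero_total_cell_rejected(self):
        counts = np.zeros((2, 1), dtype=int)
        with pytest.raises(ValueError):
            sc.log_normalize(toy_matrix(counts, ["a", "b"]))

    def test_matches_scanpy_normalization(self, rng):
        # independent oracle: scanpy normalize_total + log1p
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        counts = rng.integers(0, 30, size=(25, 8))
        counts[:, counts.sum(axis=0) == 0] += 1
        cm = toy_matrix(counts, [f"g{i}" for i in range(25)])
        ours = sc.log_normalize(cm)
        ad = anndata.AnnData(counts.T.astype(float))
        scanpy.pp.normalize_total(ad, target_sum=1e4)
        scanpy.pp.log1p(ad)
        assert np.allclose(ours, ad.X.T, atol=1e-6)


class TestVariableGenes:
    def test_identically_distributed_genes_none_pass(self, rng):
        counts = rng.poisson(5, size=(300, 60))
        norm = sc.log_normalize(toy_matrix(counts, [f"g{i}" for i in range(300)]))
        mask = sc.select_variable_genes(norm)
        # z-scores center at 0 within bins; nothing clears z >= 0.5 reliably
        assert mask.mean() < 0.35

    def test_planted_overdispersed_genes_recovered(self, rng):
        # planted genes keep the background mean (so they spread across
        # mean bins) but are bimodal on/off across cells
        n_genes, n_cells = 500, 80
        counts = rng.poisson(5, size=(n_genes, n_cells))
        planted = rng.choice(n_genes, 20, replace=False)
        for g in planted:
            on = rng.random(n_cells) < 0.5
            counts[g] = np.where(on, rng.poisson(10, n_cells), 0)
        cm = toy_matrix(counts, [f"g{i}" for i in range(n_genes)])
        norm = sc.log_normalize(cm)
        mask = sc.select_variable_genes(norm)
        assert mask[planted].all()
        # direct variance/mean oracle confirms the planted genes dominate
        raw = np.expm1(norm)
        disp = raw.var(axis=1) / np.maximum(raw.mean(axis=1), 1e-12)
        top20 = np.argsort(-disp)[:20]
        assert set(top20) == set(planted)

    def test_low_mean_gate_excludes_high_dispersion_gene(self, rng):
        counts = rng.poisson(5, size=(200, 100))
        counts[0] = 0
        counts[0, 0] = 2           # dispersed but far below the mean gate
        norm = sc.log_normalize(toy_matrix(counts, [f"g{i}" for i in range(200)]))
        raw_mean = np.expm1(norm).mean(axis=1)
        params = sc.ScParams(mean_cutoff=2 * raw_mean[0])
        mask = sc.select_variable_genes(norm, params)
        assert not mask[0]


class TestRegression:
    def test_slope_matches_normal_equations_oracle(self, rng):
        norm = rng.normal(size=(40, 60))
        cov = rng.normal(size=60)
        out = sc.regress_covariate(norm, cov)
        c = cov - cov.mean()
        for g in (0, 7, 23):
            y = norm[g] - norm[g].mean()
            slope = (y @ c) / (c @ c)
            resid = y - slope * c
            assert np.allclose(out[g], resid / resid.std())

    def test_gene_linear_in_covariate_becomes_zero(self, rng):
        cov = rng.normal(size=50)
        norm = np.vstack([2.0 * cov + 1.0, rng.normal(size=50)])
        out = sc.regress_covariate(norm, cov)
        assert np.allclose(out[0], 0.0, atol=1e-8)

    def test_constant_covariate_falls_back_with_warning(self, rng):
        norm = rng.normal(size=(5, 20))
        with pytest.warns(UserWarning, match="constant covariate"):
            out = sc.regress_covariate(norm, np.ones(20))
        centered = norm - norm.mean(axis=1, keepdims=True)
        assert np.allclose(out, centered / centered.std(axis=1, keepdims=True))


class TestPca:
    def test_variance_explained_non_increasing(self, rng):
        res = sc.pca_embed(rng.normal(size=(50, 40)), n_pcs=10)
        assert (np.diff(res.variance_explained) <= 1e-10).all()

    def test_toy_matrix_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(5, 4))         # genes x cells
        res = sc.pca_embed(X, n_pcs=3)
        cells = X.T - X.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(cells.T @ cells / (cells.shape[0] - 1))
        order = np.argsort(-evals)
        assert np.allclose(res.variance_explained, evals[order][:3], atol=1e-10)
        for j in range(3):
            ours, ref = res.loadings[:, j], evecs[:, order[j]]
            assert np.allclose(ours, ref, atol=1e-8) or \
                np.allclose(ours, -ref, atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(6, 8))
        res = sc.pca_embed(X, n_pcs=6)
        recon = (res.embedding @ res.loadings.T).T + \
            X.mean(axis=1, keepdims=True) @ np.ones((1, 1))
        centered_back = recon - recon.mean(axis=1, keepdims=True)
        assert np.allclose(centered_back, X - X.mean(axis=1, keepdims=True),
                           atol=1e-8)


class TestJackstraw:
    def test_pure_noise_rarely_flags_pcs(self):
        zero_runs = 0
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(200, 80))
            sig = sc.jackstraw_significance(X, n_pcs=5, n_reps=40, seed=seed)
            zero_runs += len(sig) == 0
        assert zero_runs >= 4

    def test_two_planted_factors_detected(self, rng):
        n_genes, n_cells = 200, 80
        X = rng.normal(size=(n_genes, n_cells))
        f1, f2 = rng.normal(size=n_cells), rng.normal(size=n_cells)
        X[:50] += 3.0 * np.outer(rng.normal(size=50), f1)
        X[50:100] += 3.0 * np.outer(rng.normal(size=50), f2)
        sig = sc.jackstraw_significance(X, n_pcs=5, n_reps=40, seed=0)
        assert {0, 1}.issubset(set(sig.tolist()))

    def test_alpha_one_flags_everything(self, rng):
        X = rng.normal(size=(40, 30))
        sig = sc.jackstraw_significance(X, n_pcs=4, n_reps=2, alpha=1.0)
        assert sig.tolist() == [0, 1, 2, 3]


class TestClustering:
    def test_two_separated_blobs_exact_recovery(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 5)), rng.normal(12, 1, (70, 5))])
        truth = np.array([0] * 60 + [1] * 70)
        labels = sc.knn_louvain(X, k=10, seed=0)
        assert labels.max() + 1 == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_labels_ordered_by_cluster_size(self, rng):
        X = np.vstack([rng.normal(0, 1, (80, 3)), rng.normal(15, 1, (30, 3))])
        labels = sc.knn_louvain(X, k=8, seed=0)
        sizes = [(labels == c).sum() for c in range(labels.max() + 1)]
        assert sizes == sorted(sizes, reverse=True)

    def test_beats_random_permutation_modularity(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(10, 1, (50, 4))])
        labels = sc.knn_louvain(X, k=10, seed=0)
        q = sc.modularity(X, labels, k=10)
        perm = np.random.default_rng(1).permutation(labels)
        assert q > sc.modularity(X, perm, k=10)

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            sc.knn_louvain(np.zeros((5, 2)), k=5)

    def test_planted_two_cluster_recovery(self, default_counts):
        params = sc.ScParams()
        f = sc.qc_filter(default_counts, params)
        norm = sc.log_normalize(f)
        hvg = sc.select_variable_genes(norm, params)
        scaled = sc.regress_covariate(norm[hvg],
                                      f.cells["percent_mito"].to_numpy())
        pca = sc.pca_embed(scaled, params.n_pcs)
        labels = sc.knn_louvain(pca.embedding, k=params.knn_k,
                                n_dims=params.n_pcs_graph, seed=0)
        ari = adjusted_rand_score(f.cells["truth_cluster"].to_numpy(), labels)
        assert ari >= 0.9


class TestMarkers:
    def build_norm(self, rng):
        # 60 cells in two clusters; gene 0 exclusive to cluster A, gene 1
        # detected in 10% of both, the rest background
        clusters = np.array([0] * 30 + [1] * 30)
        norm = rng.normal(1.0, 0.2, size=(30, 60)).clip(0)
        norm[0] = np.where(clusters == 0, rng.normal(3.0, 0.3, 60).clip(0.5), 0.0)
        detected = rng.random(60) < 0.10
        norm[1] = np.where(detected, 2.0, 0.0)
        return norm, clusters

    def test_exclusive_gene_top_ranked(self, rng):
        norm, clusters = self.build_norm(rng)
        table = sc.find_markers(norm, pd.DataFrame({"gene": [f"g{i}" for i in range(30)]}),
                                clusters)
        top = table[table["cluster"] == 0].iloc[0]
        assert top["gene"] == "g0"
        assert top["p"] < 1e-6

    def test_low_detection_gene_gated_out(self, rng):
        norm, clusters = self.build_norm(rng)
        table = sc.find_markers(norm, pd.DataFrame({"gene": [f"g{i}" for i in range(30)]}),
                                clusters)
        assert "g1" not in set(table["gene"])

    def test_identical_distributions_not_significant(self, rng):
        norm = rng.normal(1.0, 0.2, size=(20, 80)).clip(0)
        clusters = np.array([0] * 40 + [1] * 40)
        table = sc.find_markers(norm, pd.DataFrame({"gene": [f"g{i}" for i in range(20)]}),
                                clusters)
        assert (table["p"] > 1e-3).all() if len(table) else True

    def test_wilcoxon_alternative_agrees_on_strong_marker(self, rng):
        norm, clusters = self.build_norm(rng)
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(30)]})
        tw = sc.find_markers(norm, genes, clusters, test="wilcoxon")
        assert tw[tw["cluster"] == 0].iloc[0]["gene"] == "g0"

    def test_tiny_cluster_skipped_with_warning(self, rng):
        norm = rng.normal(1.0, 0.2, size=(10, 32)).clip(0)
        clusters = np.array([0] * 30 + [1] * 2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            table = sc.find_markers(norm, pd.DataFrame({"gene": [f"g{i}" for i in range(10)]}),
                                    clusters)
        assert set(table["cluster"]) <= {0}

    def test_planted_markers_recovered(self, default_counts):
        params = sc.ScParams()
        f = sc.qc_filter(default_counts, params)
        norm = sc.log_normalize(f)
        truth = (f.cells["truth_cluster"] == "cluster1").to_numpy().astype(int)
        table = sc.find_markers(norm, f.genes, truth, params)
        planted = {g for prog in syn.DEFAULT_MARKERS.values() for g in prog}
        found = set(table["gene"])
        assert len(planted & found) / len(planted) >= 0.9


class TestNoiseModelSelection:
    def test_identity_when_n_top_exceeds_genes(self, rng):
        counts = rng.poisson(5, size=(10, 20))
        cm = toy_matrix(counts, [f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning):
            out = sc.feature_select_noise_model(cm, n_top=50)
        assert set(out["gene"]) == set(cm.genes["gene"])

    def test_inflated_variance_ranks_first(self, rng):
        counts = rng.poisson(20, size=(100, 50))
        on = rng.random(50) < 0.5
        counts[0] = np.where(on, rng.poisson(60, 50), rng.poisson(2, 50))
        cm = toy_matrix(counts, [f"g{i}" for i in range(100)])
        out = sc.feature_select_noise_model(cm, n_top=5)
        assert "g0" in set(out["gene"])
        # direct CV^2 oracle: g0's CV^2 is far above the cohort at its mean
        cv2 = counts.var(axis=1) / counts.mean(axis=1) ** 2
        assert cv2[0] > 5 * np.median(cv2[1:])

    def test_gene_order_permutation_invariant(self, rng):
        counts = rng.poisson(10, size=(40, 30))
        cm = toy_matrix(counts, [f"g{i}" for i in range(40)])
        perm = np.random.default_rng(3).permutation(40)
        cm_p = toy_matrix(counts[perm], [f"g{i}" for i in perm])
        a = sc.feature_select_noise_model(cm, n_top=10)
        b = sc.feature_select_noise_model(cm_p, n_top=10)
        assert set(a["gene"]) == set(b["gene"])


class TestEnrichment:
    def test_disjoint_term_p_is_one(self):
        universe = {f"g{i}" for i in range(20)}
        table, _ = sc.enrichment_network({"g0", "g1"}, {"t": {"g10", "g11"}},
                                         universe)
        assert table["p"].item() == pytest.approx(1.0)

    def test_exact_hypergeometric_tail(self):
        # universe 10, term 5, query 5, overlap 5: p = 1 / C(10,5)
        universe = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}
        table, _ = sc.enrichment_network(query, {"t": set(query)}, universe)
        assert table["p"].item() == pytest.approx(1 / 252, rel=1e-9)

    def test_jaccard_edges(self):
        universe = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(10)}
        shared = {f"g{i}" for i in range(10)}
        annotation = {"t1": shared, "t2": set(shared),
                      "t3": {f"g{i}" for i in range(10, 20)} | {"g0"}}
        params = sc.ScParams(term_p=0.05, fdr_q=0.5)
        table, graph = sc.enrichment_network(query, annotation, universe, params)
        kept = set(table[table["kept"]]["term"])
        assert {"t1", "t2"} <= kept
        assert graph.has_edge("t1", "t2")          # identical sets: J = 1
        if "t3" in kept:
            assert not graph.has_edge("t1", "t3")  # J = 1/20 < 0.25

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            sc.enrichment_network({"a"}, {"t": {"a"}}, set())


class TestBenchmark:
    def test_reports_both_dispersion_modes(self, default_counts):
        out = sc.variable_gene_benchmark(default_counts)
        assert set(out) == {"n_cells_pass_qc", "n_genes_pass_qc",
                            "n_variable_z_scored", "n_variable_raw"}
        assert out["n_variable_z_scored"] > 0
        again = sc.variable_gene_benchmark(default_counts)
        assert out == again
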