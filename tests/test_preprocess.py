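"""Filtering, normalisation, variable-gene selection and graph construction."""

import numpy as np
import pytest

from fuseclust.preprocess import (EmptyDatasetError, RawCountMatrix,
                                  build_cell_graph, filter_empty,
                                  normalize_and_select, preprocess, zscore)


def make_raw(counts, labels=None):
    return RawCountMatrix(counts=np.asarray(counts), labels=labels)


class TestFilterEmpty:
    def test_zero_row_dropped(self):
        raw = make_raw([[1, 2, 3], [0, 0, 0], [4, 0, 5]])
        out = filter_empty(raw)
        assert out.counts.shape == (2, 3)
        assert out.cell_ids == ["cell_0", "cell_2"]

    def test_identity_when_nothing_empty(self):
        raw = make_raw([[1, 2], [3, 4]])
        out = filter_empty(raw)
        np.testing.assert_array_equal(out.counts, raw.counts)

    def test_matches_brute_force_survivor_scan(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(5, 5))
        counts[2, :] = 0
        counts[:, 1] = 0
        counts[:, 4] = 0
        raw = make_raw(counts)
        out = filter_empty(raw)
        keep_cells = [i for i in range(5) if counts[i].sum() > 0]
        keep_genes = [j for j in range(5) if counts[:, j].sum() > 0]
        assert out.cell_ids == [f"cell_{i}" for i in keep_cells]
        assert out.gene_ids == [f"gene_{j}" for j in keep_genes]
        np.testing.assert_array_equal(out.counts,
                                      counts[np.ix_(keep_cells, keep_genes)])

    def test_all_empty_raises(self):
        with pytest.raises(EmptyDatasetError):
            filter_empty(make_raw(np.zeros((3, 3), dtype=int)))

    def test_labels_follow_cells(self):
        raw = make_raw([[1, 1], [0, 0], [2, 2]], labels=["a", "b", "c"])
        out = filter_empty(raw)
        assert list(out.labels) == ["a", "c"]


class TestRawCountValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_raw([[1, -1], [0, 2]])

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            RawCountMatrix(counts=np.ones((2, 2), int), cell_ids=["a"],
                           gene_ids=["g1", "g2"])


class TestNormalizeAndSelect:
    def test_identical_cells_have_identical_rows(self):
        raw = make_raw([[5, 3, 2], [5, 3, 2], [1, 8, 1]])
        out = normalize_and_select(raw, n_hvg=3)
        np.testing.assert_allclose(out.x_norm[0], out.x_norm[1])

    def test_no_selection_keeps_all_genes(self):
        raw = make_raw(np.random.default_rng(1).poisson(2.0, (6, 4)) + 1)
        out = normalize_and_select(raw, n_hvg=4)
        assert sorted(out.selected_genes) == sorted(raw.gene_ids)

    def test_hvg_matches_dispersion_ranking_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(rng.uniform(0.5, 8.0, size=(1, 20)),
                             size=(10, 20)) + (rng.random((10, 20)) < 0.1)
        raw = make_raw(counts.astype(int))
        out = normalize_and_select(raw, n_hvg=5)
        # independent reimplementation: variance/mean of normalised counts
        lib = counts.sum(axis=1).astype(float)
        norm = counts / (lib / np.median(lib))[:, None]
        disp = [norm[:, j].var() / norm[:, j].mean() if norm[:, j].mean() > 0
                else 0.0 for j in range(20)]
        top5 = set(np.argsort(-np.asarray(disp), kind="stable")[:5])
        assert {int(g.split("_")[1]) for g in out.selected_genes} == top5

    def test_size_factors_definition(self):
        counts = np.array([[10, 0], [0, 20], [5, 5]])
        out = normalize_and_select(make_raw(counts), n_hvg=2)
        lib = counts.sum(axis=1)
        np.testing.assert_allclose(out.size_factors, lib / np.median(lib))

    def test_r_prime_holds_untransformed_counts(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3.0, (8, 6)) + 1
        out = normalize_and_select(make_raw(counts), n_hvg=4)
        cols = [int(g.split("_")[1]) for g in out.selected_genes]
        np.testing.assert_array_equal(out.r_prime, counts[:, cols])


class TestZscore:
    def test_closed_form_column(self):
        out = zscore(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.224744871, 0.0, 1.224744871],
                                   atol=1e-8)

    def test_constant_column_becomes_zero(self):
        out = zscore(np.array([[2.0, 1.0], [2.0, 3.0], [2.0, 5.0]]))
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_moments_recomputed(self):
        x = np.random.default_rng(5).normal(2.0, 3.0, size=(6, 4))
        out = zscore(x)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=0), 1.0, atol=1e-10)

    def test_deterministic(self):
        x = np.random.default_rng(5).normal(size=(6, 4))
        np.testing.assert_array_equal(zscore(x), zscore(x))


class TestCellGraph:
    def test_kernel_at_zero_distance_and_sigma(self):
        # duplicate points -> d=0 -> weight exp(0)=1 (before self-loop rule)
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0], [0.0, 3.0],
                        [3.0, 3.0], [1.0, 1.0]])
        g = build_cell_graph(pts, k=2, n_pca=2)
        assert g.adjacency[0, 1] == pytest.approx(1.0)

    def test_weight_at_one_sigma(self):
        # equally spaced collinear points with k=1: every sigma equals the
        # spacing, so each nearest-neighbour weight is exp(-1/2)
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        g = build_cell_graph(pts, k=1, n_pca=2)
        assert g.adjacency[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-10)
        assert g.adjacency[1, 2] == pytest.approx(np.exp(-0.5), abs=1e-10)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        k = 2
        g = build_cell_graph(pts, k=k, n_pca=2)
        # brute-force double loop
        n = 6
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        sigma = np.array([np.sort(d[i])[k] for i in range(n)])
        a = np.zeros((n, n))
        for i in range(n):
            knn_i = np.argsort(d[i])[1:k + 1]
            for j in range(n):
                if i == j:
                    continue
                knn_j = np.argsort(d[j])[1:k + 1]
                if j in knn_i or i in knn_j:
                    a[i, j] = np.exp(-d[i, j] ** 2 / (2 * sigma[i] * sigma[j]))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(g.adjacency, a, atol=1e-8)
        deg = a.sum(axis=1)
        norm = a / np.sqrt(np.outer(deg, deg))
        np.testing.assert_allclose(g.adjacency_norm, norm, atol=1e-8)

    def test_adjacency_bounds_and_symmetry(self, tiny_processed):
        data, graph, _ = tiny_processed
        a = graph.adjacency
        assert np.all(a >= 0) and np.all(a <= 1)
        np.testing.assert_allclose(a, a.T)

    def test_normalization_identity(self, tiny_processed):
        _, graph, _ = tiny_processed
        deg = graph.adjacency.sum(axis=1)
        expected = graph.adjacency / np.sqrt(np.outer(deg, deg))
        np.testing.assert_allclose(graph.adjacency_norm, expected, atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 3))
        perm = rng.permutation(12)
        g1 = build_cell_graph(pts, k=3, n_pca=3)
        g2 = build_cell_graph(pts[perm], k=3, n_pca=3)
        np.testing.assert_allclose(g2.adjacency, g1.adjacency[np.ix_(perm, perm)],
                                   atol=1e-10)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            build_cell_graph(np.zeros((4, 2)), k=4, n_pca=2)

    def test_duplicate_points_sigma_floored(self):
        pts = np.zeros((5, 2))
        g = build_cell_graph(pts, k=2, n_pca=2)
        assert np.all(g.per_cell_sigma > 0)
        assert np.all(np.isfinite(g.adjacency))


def test_preprocess_pipeline_shapes(tiny_dataset):
    raw, _ = tiny_dataset
    data, graph = preprocess(raw, n_hvg=40, k=10)
    n = data.n_cells
    assert data.x_zscore.shape == (n, 40)
    assert data.r_prime.shape == (n, 40)
    assert graph.adjacency.shape == (n, n)
    assert np.all(data.size_factors > 0)
    # z-score invariant (constant columns excluded by construction)
    nonconst = data.x_norm.std(axis=0) > 0
    assert np.all(np.abs(data.x_zscore[:, nonconst].mean(axis=0)) < 1e-6)
    assert np.all(np.abs(data.x_zscore[:, nonconst].var(axis=0) - 1) < 1e-4)
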