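"""Spatial mixture tests: knn graph, Potts energy, ICM-EM, selection."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from transst.containers import NeighborGraph, SimConfig, SpatialCoords
from transst.pipeline import adjusted_rand_index
from transst.simulate import simulate_dataset
from transst.spgmm import (
    SpatialGMM,
    _symmetric_adjacency,
    build_knn_graph,
    fit_gmm,
    icm_em_fit,
    line_search_beta,
    potts_energy,
    select_K,
)
from transst.transfer import als_fit
from transst.containers import TransferConfig
from transst.pldr import fit_pldr


class TestKnnGraph:
    def test_collinear_tie_goes_to_lower_index(self):
        coords = SpatialCoords(np.array([[0.0, 0], [1, 0], [2, 0]]))
        g = build_knn_graph(coords, 1)
        assert g.neighbors[1, 0] == 0  # equidistant: lower index wins

    def test_grid_interior_rook_neighbors(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        coords = SpatialCoords(np.column_stack([xs.ravel(), ys.ravel()]))
        g = build_knn_graph(coords, 4)
        i = 5 * 10 + 5  # an interior spot
        expect = {i - 1, i + 1, i - 10, i + 10}
        assert set(g.neighbors[i]) == expect

    def test_matches_brute_force(self, rng):
        pts = rng.standard_normal((200, 2))
        g = build_knn_graph(SpatialCoords(pts), 5)
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        ref = np.argsort(d, axis=1, kind="stable")[:, :5]
        assert np.array_equal(g.neighbors, ref)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError, match="k="):
            build_knn_graph(SpatialCoords(rng.standard_normal((4, 2))), 4)


class TestPottsEnergy:
    def test_homogeneous_field_zero(self):
        g = build_knn_graph(SpatialCoords(np.arange(10.0)[:, None] * [1, 0]), 2)
        assert potts_energy(np.ones(10, dtype=int), g, 1.3) == 0.0

    def test_beta_zero_any_labeling(self, rng):
        g = build_knn_graph(SpatialCoords(rng.standard_normal((20, 2))), 3)
        labels = rng.integers(1, 4, 20)
        assert potts_energy(labels, g, 0.0) == 0.0

    def test_cycle_enumeration_oracle(self):
        """4-node cycle, alternating labels, symmetric 2-neighbor lists:
        energy equals the brute-force double sum."""
        neighbors = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
        g = NeighborGraph(neighbors=neighbors, k=2)
        labels = np.array([1, 2, 1, 2])
        beta = 1.0
        expect = 0.5 * sum(
            beta * (labels[i] != labels[j])
            for i in range(4) for j in neighbors[i]
        )
        assert potts_energy(labels, g, beta) == expect == 4.0


def _blob_embedding(rng, n_side=8, sep=6.0):
    """Two Gaussian blobs occupying the left/right halves of a grid."""
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
    coords = SpatialCoords(np.column_stack([xs.ravel(), ys.ravel()]).astype(float))
    labels = (xs.ravel() >= n_side // 2).astype(int) + 1
    V = rng.standard_normal((n_side * n_side, 2))
    V[labels == 2] += sep
    return V, coords, labels


class TestIcmEm:
    def test_beta_zero_reduces_to_gmm_bitwise(self, rng):
        V = rng.standard_normal((120, 3))
        V[:60] += 4.0
        coords = SpatialCoords(rng.standard_normal((120, 2)))
        g = build_knn_graph(coords, 5)
        spatial = icm_em_fit(V, g, 2, 0.0, seed=11)
        plain = fit_gmm(V, 2, seed=11)
        assert np.array_equal(spatial.labels, plain.labels)
        assert np.array_equal(spatial.responsibilities, plain.responsibilities)

    def test_separable_blobs_recovered(self, rng):
        V, coords, truth = _blob_embedding(rng)
        g = build_knn_graph(coords, 5)
        fit = icm_em_fit(V, g, 2, 1.0, seed=0)
        assert adjusted_rand_index(fit.labels, truth) == 1.0

    def test_icm_local_optimality(self, rng):
        """At convergence no single-spot relabeling improves the ICM
        objective log N(v_i; mu_k, Sigma_k) + beta * votes_k."""
        xs, ys = np.meshgrid(np.arange(5), np.arange(5))
        coords = SpatialCoords(np.column_stack([xs.ravel(), ys.ravel()]).astype(float))
        V = rng.standard_normal((25, 1))
        V[xs.ravel() >= 2] += 3.0
        g = build_knn_graph(coords, 4)
        beta = 0.8
        fit = icm_em_fit(V, g, 2, beta, seed=1)
        from transst.spgmm import _log_gauss

        A = _symmetric_adjacency(g, "union").toarray()
        logN = _log_gauss(V, fit.cluster_means, fit.cluster_covs)
        Z = np.eye(2)[fit.labels - 1]
        votes = A @ Z
        obj = logN + beta * votes
        for i in range(25):
            assert obj[i, fit.labels[i] - 1] >= obj[i].max() - 1e-10

    def test_responsibilities_normalized_and_consistent(self, rng):
        V, coords, _ = _blob_embedding(rng)
        g = build_knn_graph(coords, 5)
        fit = icm_em_fit(V, g, 2, 0.6, seed=2)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-8)
        assert np.array_equal(fit.labels, np.argmax(fit.responsibilities, axis=1) + 1)

    def test_pseudo_loglik_trace_monotone(self, rng):
        for trial in range(5):
            V, coords, _ = _blob_embedding(rng, sep=2.0)
            g = build_knn_graph(coords, 5)
            fit = icm_em_fit(V, g, 2, 0.7, seed=trial)
            tr = np.asarray(fit.pseudo_loglik_trace)
            assert np.all(np.diff(tr) >= -1e-6 * np.maximum(1.0, np.abs(tr[:-1])))


class TestLineSearch:
    def test_singleton_grid_is_plain_gmm(self, rng):
        V, coords, _ = _blob_embedding(rng)
        g = build_knn_graph(coords, 5)
        fit = line_search_beta(V, g, 2, grid=[0.0], seed=3)
        plain = fit_gmm(V, 2, seed=3)
        assert fit.beta == 0.0
        assert np.array_equal(fit.labels, plain.labels)

    def test_unstructured_labels_select_zero(self):
        """i.i.d. cluster fields carry no spatial signal: beta -> 0."""
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, beta_true=0.0, grid_height=30, grid_width=30,
                            n_source=600)
            data = simulate_dataset(cfg)
            g = build_knn_graph(data.coords, 5)
            model = fit_pldr(data.source, q=5)
            X = data.target_expr.values - data.target_expr.values.mean(0)
            _, V = als_fit(X, model.loading, 10.0, TransferConfig())
            fit = line_search_beta(V, g, 4, seed=seed)
            hits += fit.beta == 0.0
        assert hits >= 7

    def test_smooth_field_selects_strong_beta(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, grid_height=30, grid_width=30, n_source=600)
            data = simulate_dataset(cfg)
            g = build_knn_graph(data.coords, 5)
            model = fit_pldr(data.source, q=5)
            X = data.target_expr.values - data.target_expr.values.mean(0)
            _, V = als_fit(X, model.loading, 10.0, TransferConfig())
            fit = line_search_beta(V, g, 4, seed=seed)
            hits += fit.beta >= 0.5
        assert hits >= 8


class TestSelectK:
    def test_singleton_range_returns_that_fit(self, rng):
        V, coords, _ = _blob_embedding(rng, n_side=10)
        g = build_knn_graph(coords, 5)
        fit = select_K(V, g, [4], seed=0)
        assert fit.K == 4
        assert np.isfinite(fit.criterion_value)

    def test_single_blob_selects_one(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            V = rng.standard_normal((150, 2))
            coords = SpatialCoords(rng.uniform(0, 12, (150, 2)))
            g = build_knn_graph(coords, 5)
            fit = select_K(V, g, [1, 2, 3], seed=seed)
            hits += fit.K == 1
        assert hits >= 8


class TestEstimatorInterface:
    def test_fit_predict_and_params(self, rng):
        V, coords, truth = _blob_embedding(rng)
        est = SpatialGMM(n_clusters=2, beta=1.0, random_state=0)
        labels = est.fit_predict(V, coords=coords.coords)
        assert adjusted_rand_index(labels, truth) == 1.0
        assert est.beta_ == 1.0 and est.n_clusters_ == 2
        assert est.get_params()["n_neighbors"] == 5

    def test_coords_required(self, rng):
        with pytest.raises(ValueError, match="coordinates"):
            SpatialGMM(n_clusters=2).fit(rng.standard_normal((30, 2)))
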