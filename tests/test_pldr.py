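"""Supervised factor model (pLDR) tests: EM correctness and oracles."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.stats import multivariate_normal

from transst.containers import ExpressionMatrix, FactorModel, LabeledSource, SimConfig
from transst.io import pca_scores_loadings
from transst.pldr import PLDR, fit_pldr, pldr_loglik, project_source
from transst.simulate import simulate_dataset


def _source(X, labels):
    expr = ExpressionMatrix(X, [f"g{j}" for j in range(X.shape[1])],
                            [f"s{i}" for i in range(X.shape[0])])
    return LabeledSource(expr, labels)


def _single_cluster_data(rng, n=300, p=12, q=2, sigma=0.3):
    W = rng.standard_normal((p, q))
    U = rng.standard_normal((n, q))
    X = U @ W.T + sigma * rng.standard_normal((n, p))
    return X, W


class TestFitPldr:
    def test_noiseless_limit_recovers_span(self, rng):
        X, W = _single_cluster_data(rng, sigma=1e-8)
        model = fit_pldr(_source(X, np.ones(len(X), dtype=int)), q=2)
        angles = subspace_angles(model.loading, W)
        assert np.max(angles) < 1e-3

    def test_ppca_closed_form_loglik(self, rng):
        """With an isotropic residual and a single standard-normal latent
        cluster, the marginal likelihood is exactly probabilistic PCA;
        the model loglik at the PPCA ML parameters must match the
        closed form, and the EM fit must do at least as well."""
        n, p, q = 400, 10, 2
        W = rng.standard_normal((p, q))
        X = rng.standard_normal((n, q)) @ W.T + 0.5 * rng.standard_normal((n, p))
        S = X.T @ X / n  # model has no intercept: second-moment matrix
        evals, evecs = np.linalg.eigh(S)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        sigma2 = evals[q:].mean()
        W_ml = evecs[:, :q] @ np.diag(np.sqrt(evals[:q] - sigma2))
        C = W_ml @ W_ml.T + sigma2 * np.eye(p)
        closed = -n / 2 * (p * np.log(2 * np.pi) + np.linalg.slogdet(C)[1]
                           + np.trace(np.linalg.solve(C, S)))
        labels = np.ones(n, dtype=int)
        ppca_model = FactorModel(W_ml, np.full(p, sigma2), np.zeros((1, q)),
                                 np.eye(q)[None])
        ours = pldr_loglik(ppca_model, _source(X, labels))
        assert ours == pytest.approx(closed, abs=1e-6)
        fit = fit_pldr(_source(X, labels), q=q)
        assert fit.loglik_trace[-1] >= closed - 1e-6

    def test_supervised_beats_unsupervised_recovery(self):
        """Knowing the labels must help recover the loading span: mean
        principal angle of the supervised fit below PCA's, averaged
        over 10 simulated sources (K=4, n1=1000, p=50, q=5)."""
        sup, unsup = [], []
        for seed in range(10):
            cfg = SimConfig(seed=seed, p=50, n_source=1000)
            data = simulate_dataset(cfg)
            model = fit_pldr(data.source, q=5)
            _, pca_loadings = pca_scores_loadings(data.source.expr.values, 5)
            sup.append(np.mean(subspace_angles(model.loading, data.true_loading)))
            unsup.append(np.mean(subspace_angles(pca_loadings, data.true_loading)))
        assert np.mean(sup) < np.mean(unsup)

    def test_trace_monotone_and_variance_floor(self, small_sim):
        _, data = small_sim
        model = fit_pldr(data.source, q=5)
        trace = model.loglik_trace
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))
        assert np.all(model.resid_var >= 1e-8)
        for cov in model.cluster_covs:
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_angle_shrinks_with_noise(self):
        """Loading recovery improves as the residual noise shrinks."""
        angles = []
        for sigma in (2.0, 0.5, 0.05):
            rng = np.random.default_rng(3)
            X, W = _single_cluster_data(rng, n=500, sigma=sigma)
            model = fit_pldr(_source(X, np.ones(500, dtype=int)), q=2)
            angles.append(np.max(subspace_angles(model.loading, W)))
        assert angles[0] > angles[1] > angles[2]

    def test_small_cluster_rejected(self, rng):
        X = rng.standard_normal((20, 6))
        labels = np.r_[np.ones(17, dtype=int), 2 * np.ones(3, dtype=int)]
        with pytest.raises(ValueError, match="cluster 2"):
            fit_pldr(_source(X, labels), q=3)


class TestProjectSource:
    def test_noiseless_limit_is_least_squares(self, rng):
        X, W = _single_cluster_data(rng, n=200, sigma=1e-6)
        src = _source(X, np.ones(200, dtype=int))
        model = fit_pldr(src, q=2)
        emb = project_source(model, src)
        Wh = model.loading
        lstsq = np.linalg.solve(Wh.T @ Wh, Wh.T @ X.T).T
        assert np.allclose(emb.scores, lstsq, atol=1e-3)

    def test_prior_consistent_point(self, rng):
        p, q = 8, 2
        model = FactorModel(
            loading=rng.standard_normal((p, q)),
            resid_var=np.full(p, 0.5),
            cluster_means=rng.standard_normal((2, q)),
            cluster_covs=np.stack([np.eye(q)] * 2),
        )
        mu1 = model.cluster_means[0]
        x = model.loading @ mu1
        emb = project_source(model, _source(x[None, :], np.array([1])))
        assert np.allclose(emb.scores[0], mu1, atol=1e-10)

    def test_conditional_gaussian_oracle(self, rng):
        """Posterior mean matches direct evaluation of the Gaussian
        conditional-mean formula on a small instance."""
        p, q = 6, 2
        W = rng.standard_normal((p, q))
        lam = rng.uniform(0.3, 1.0, p)
        mu = rng.standard_normal(q)
        Sigma = np.eye(q) + 0.3 * np.ones((q, q))
        model = FactorModel(W, lam, mu[None], Sigma[None])
        X = rng.standard_normal((5, p))
        emb = project_source(model, _source(X, np.ones(5, dtype=int)))
        # u|x ~ N(mu + Sigma W' C^{-1} (x - W mu), .) with C = W Sigma W' + Lam
        C = W @ Sigma @ W.T + np.diag(lam)
        for i in range(5):
            expect = mu + Sigma @ W.T @ np.linalg.solve(C, X[i] - W @ mu)
            assert np.allclose(emb.scores[i], expect, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        X, _ = _single_cluster_data(rng, n=50, p=12)
        src = _source(X, np.ones(50, dtype=int))
        model = fit_pldr(src, q=2)
        bad = _source(X[:, :7], np.ones(50, dtype=int))
        with pytest.raises(ValueError):
            project_source(model, bad)


class TestLoglik:
    def test_scalar_case(self):
        """n=1, p=1: matches the univariate normal log-density."""
        model = FactorModel(np.array([[0.0]]), np.array([2.0]),
                            np.zeros((1, 1)), np.full((1, 1, 1), 1e-12) + np.eye(1) * 1e-6)
        src = _source(np.array([[1.5]]), np.array([1]))
        var = 2.0 + float(model.loading[0, 0] ** 2 * model.cluster_covs[0, 0, 0])
        expect = -0.5 * (np.log(2 * np.pi * var) + 1.5 ** 2 / var)
        assert pldr_loglik(model, src) == pytest.approx(expect, abs=1e-10)

    def test_row_duplication_doubles(self, rng):
        X, _ = _single_cluster_data(rng, n=30, p=8)
        src = _source(X, np.ones(30, dtype=int))
        model = fit_pldr(src, q=2, max_iter=5)
        ll1 = pldr_loglik(model, src)
        X2 = np.vstack([X, X])
        ll2 = pldr_loglik(model, _source(X2, np.ones(60, dtype=int)))
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_dense_mvn_oracle(self, rng):
        """Woodbury evaluation equals a dense multivariate-normal sum."""
        n, p, q, K = 20, 6, 2, 2
        W = rng.standard_normal((p, q))
        lam = rng.uniform(0.2, 1.5, p)
        mus = rng.standard_normal((K, q))
        covs = np.stack([np.eye(q) * s for s in (1.0, 2.0)])
        model = FactorModel(W, lam, mus, covs)
        X = rng.standard_normal((n, p))
        labels = rng.integers(1, K + 1, n)
        labels[:K] = [1, 2]  # both clusters present
        expect = 0.0
        for i in range(n):
            k = labels[i] - 1
            expect += multivariate_normal.logpdf(
                X[i], mean=W @ mus[k], cov=W @ covs[k] @ W.T + np.diag(lam))
        ours = pldr_loglik(model, _source(X, labels))
        assert ours == pytest.approx(expect, abs=1e-8)


class TestEstimatorInterface:
    def test_sklearn_params_and_transform(self, rng):
        X, _ = _single_cluster_data(rng, n=100, p=10)
        est = PLDR(n_components=2)
        assert est.get_params()["n_components"] == 2
        est.fit(X, np.ones(100, dtype=int))
        assert est.loading_.shape == (10, 2)
        scores_lab = est.transform(X, np.ones(100, dtype=int))
        scores_unlab = est.transform(X)
        assert scores_lab.shape == (100, 2)
        # single cluster: labeled and unlabeled projections coincide
        assert np.allclose(scores_lab, scores_unlab, atol=1e-10)
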