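"""Step 1: supervised probabilistic linear dimension reduction (pLDR).

Model: for source row i with known cluster label z_i = k,

    x_i = W0 u_i + eps_i,   eps_i ~ N(0, Lambda)  (Lambda diagonal),
    u_i | z_i = k ~ N(mu_k, Sigma_k).

Because the labels are known, this is a mixture of factor analyzers
with a shared loading and fixed assignment, fit by EM.  The quantity of
interest downstream is the estimated loading W0; the Step-1 cluster
parameters are disposable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import Embedding, FactorModel, LabeledSource
from .io import pca_scores_loadings

__all__ = ["PLDR", "fit_pldr", "project_source", "pldr_loglik"]

_VAR_FLOOR = 1e-8
_JITTER = 1e-6
_MONOTONE_SLACK = 1e-8


class PLDR(BaseEstimator, TransformerMixin):
    """Supervised Gaussian factor model with cluster-specific latent priors.

    Parameters
    ----------
    n_components : int
        Latent dimension q (must satisfy q < p and every cluster size > q).
    tol : float, default 1e-6
        Relative log-likelihood change for EM convergence.
    max_iter : int, default 100
        Maximum EM iterations.

    Attributes
    ----------
    loading_ : ndarray (p, q)
        Estimated shared loading matrix W0.
    resid_var_ : ndarray (p,)
        Diagonal residual variances (floored at 1e-8).
    cluster_means_ : ndarray (K, q)
    cluster_covs_ : ndarray (K, q, q)
    loglik_trace_ : list of float
        Observed-data log-likelihood at each EM iteration (non-decreasing).
    """

    def __init__(self, n_components: int = 15, tol: float = 1e-6, max_iter: int = 100):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        n, p = X.shape
        q = self.n_components
        if q >= p:
            raise ValueError(f"n_components={q} must be smaller than p={p}")
        labels = np.unique(y)
        if labels.min() < 1:
            raise ValueError("labels must be 1-based")
        K = int(labels.max())
        groups = [np.flatnonzero(y == k + 1) for k in range(K)]
        for k, idx in enumerate(groups):
            if idx.size <= q:
                raise ValueError(f"cluster {k + 1} has {idx.size} members; needs > q={q}")

        # --- initialization from PCA on the (uncentered) source
        scores, W = _svd_init(X, q)
        mus = np.stack([scores[idx].mean(axis=0) for idx in groups])
        covs = np.stack([_regularized_cov(scores[idx], mus[k]) for k, idx in enumerate(groups)])
        resid = X - scores @ W.T
        lam = np.maximum(np.mean(resid * resid, axis=0), 1e-4)

        trace: list[float] = []
        xx_colsum = np.einsum("ij,ij->j", X, X)
        for _ in range(self.max_iter):
            # --- E-step: Gaussian posterior of u_i given (x_i, z_i = k)
            Li = 1.0 / lam
            WtLi = W.T * Li[None, :]           # (q, p)
            B = WtLi @ W                       # (q, q)
            M = np.empty((n, q))
            Cks = np.empty((K, q, q))          # posterior covariances, one per cluster
            ll = 0.0
            for k, idx in enumerate(groups):
                Sk_chol = cho_factor(covs[k], lower=True)
                Sk_inv = cho_solve(Sk_chol, np.eye(q))
                A_chol = cho_factor(Sk_inv + B, lower=True)
                rhs = WtLi @ X[idx].T + (Sk_inv @ mus[k])[:, None]
                M[idx] = cho_solve(A_chol, rhs).T
                Cks[k] = cho_solve(A_chol, np.eye(q))
                ll += _marginal_loglik_block(X[idx], W, lam, mus[k], covs[k], Li, B)
            if trace and ll < trace[-1] - _MONOTONE_SLACK * max(1.0, abs(trace[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased from {trace[-1]:.10g} to {ll:.10g}"
                )
            converged = bool(trace) and abs(ll - trace[-1]) < self.tol * (abs(trace[-1]) + 1.0)
            trace.append(ll)
            if converged:
                break
            # --- M-step: weighted least squares for W, per-gene residual
            # variances for Lambda, moment updates for (mu_k, Sigma_k)
            Csum = np.einsum("k,kab->ab", np.array([len(g) for g in groups], dtype=float), Cks)
            Suu = M.T @ M + Csum
            Sxu = X.T @ M
            W = np.linalg.solve(Suu, Sxu.T).T
            lam = np.maximum((xx_colsum - np.einsum("jq,jq->j", W, Sxu)) / n, _VAR_FLOOR)
            for k, idx in enumerate(groups):
                mus[k] = M[idx].mean(axis=0)
                d = M[idx] - mus[k]
                covs[k] = _ensure_pd(Cks[k] + d.T @ d / idx.size)
        self.loading_ = W
        self.resid_var_ = lam
        self.cluster_means_ = mus
        self.cluster_covs_ = covs
        self.loglik_trace_ = trace
        self.n_features_in_ = p
        return self

    def transform(self, X, y=None):
        """Posterior mean of the latent scores.

        With labels ``y`` (1-based) the cluster-conditional posterior
        mean is returned; without labels, the posterior cluster
        probabilities (uniform prior over clusters) weight the
        per-cluster means.
        """
        check_is_fitted(self, "loading_")
        X = check_array(X, dtype=np.float64)
        return _posterior_means(
            X, self.loading_, self.resid_var_, self.cluster_means_, self.cluster_covs_, y
        )

    def score(self, X, y):
        check_is_fitted(self, "loading_")
        model = self._to_model()
        return pldr_loglik(model, LabeledSource(_bare_expr(X), np.asarray(y, dtype=int)))

    def _to_model(self) -> FactorModel:
        return FactorModel(
            loading=self.loading_,
            resid_var=self.resid_var_,
            cluster_means=self.cluster_means_,
            cluster_covs=self.cluster_covs_,
            loglik_trace=list(self.loglik_trace_),
        )


def _svd_init(X: np.ndarray, q: int):
    """PCA-style initialization on the uncentered matrix (the mean is
    captured through the latent cluster means, so the span must include
    the mean direction)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[q - 1] <= s[0] * 1e-12:
        # degenerate directions: pad with small random-free identity columns
        s = np.maximum(s, s[0] * 1e-12)
    scores = U[:, :q] * s[:q]
    return scores, Vt[:q].T


def _regularized_cov(S: np.ndarray, mu: np.ndarray) -> np.ndarray:
    d = S - mu
    C = d.T @ d / S.shape[0]
    return _ensure_pd(C)


def _ensure_pd(C: np.ndarray) -> np.ndarray:
    C = 0.5 * (C + C.T)
    q = C.shape[0]
    min_eig = np.linalg.eigvalsh(C).min()
    if min_eig < _VAR_FLOOR:
        warnings.warn("singular posterior covariance; adding 1e-6 ridge", stacklevel=3)
        C = C + (_JITTER + max(0.0, -min_eig)) * np.eye(q)
    return C


def _marginal_loglik_block(Xk, W, lam, mu, Sigma, Li, B):
    """Sum of log N(x_i; W mu, W Sigma W' + Lambda) over a cluster block,
    via the Woodbury identity and the matrix determinant lemma."""
    nk, p = Xk.shape
    L_S = np.linalg.cholesky(Sigma)
    inner = np.eye(Sigma.shape[0]) + L_S.T @ B @ L_S
    sign, logdet_inner = np.linalg.slogdet(inner)
    if sign <= 0:
        raise np.linalg.LinAlgError("marginal covariance not positive definite")
    logdet = np.sum(np.log(lam)) + logdet_inner
    D = Xk - (W @ mu)[None, :]
    DLi = D * Li[None, :]
    t = DLi @ W                      # (nk, q)
    Sigma_inv = cho_solve(cho_factor(Sigma, lower=True), np.eye(Sigma.shape[0]))
    A = Sigma_inv + B
    sol = np.linalg.solve(A, t.T).T
    quad = np.einsum("ij,ij->i", DLi, D) - np.einsum("ij,ij->i", t, sol)
    return -0.5 * (nk * (p * np.log(2 * np.pi) + logdet) + quad.sum())


def _posterior_means(X, W, lam, mus, covs, y=None):
    n, p = X.shape
    if p != W.shape[0]:
        raise ValueError(f"X has {p} genes but the model was fit with {W.shape[0]}")
    q = W.shape[1]
    K = mus.shape[0]
    Li = 1.0 / lam
    WtLi = W.T * Li[None, :]
    B = WtLi @ W
    Mk = np.empty((K, n, q))
    for k in range(K):
        Sk_inv = cho_solve(cho_factor(covs[k], lower=True), np.eye(q))
        A = Sk_inv + B
        rhs = WtLi @ X.T + (Sk_inv @ mus[k])[:, None]
        Mk[k] = np.linalg.solve(A, rhs).T
    if y is not None:
        y = np.asarray(y, dtype=int)
        if y.shape != (n,):
            raise ValueError("labels length must match rows of X")
        if y.min() < 1 or y.max() > K:
            raise ValueError("labels out of range for the fitted model")
        return Mk[y - 1, np.arange(n)]
    # unlabeled: weight by marginal cluster posteriors under a uniform prior
    logp = np.empty((n, K))
    for k in range(K):
        logp[:, k] = _marginal_logpdf_rows(X, W, lam, mus[k], covs[k], Li, B)
    logp -= logp.max(axis=1, keepdims=True)
    R = np.exp(logp)
    R /= R.sum(axis=1, keepdims=True)
    return np.einsum("nk,knq->nq", R, Mk)


def _marginal_logpdf_rows(X, W, lam, mu, Sigma, Li, B):
    p = X.shape[1]
    q = Sigma.shape[0]
    L_S = np.linalg.cholesky(Sigma)
    inner = np.eye(q) + L_S.T @ B @ L_S
    _, logdet_inner = np.linalg.slogdet(inner)
    logdet = np.sum(np.log(lam)) + logdet_inner
    D = X - (W @ mu)[None, :]
    DLi = D * Li[None, :]
    t = DLi @ W
    Sigma_inv = cho_solve(cho_factor(Sigma, lower=True), np.eye(q))
    sol = np.linalg.solve(Sigma_inv + B, t.T).T
    quad = np.einsum("ij,ij->i", DLi, D) - np.einsum("ij,ij->i", t, sol)
    return -0.5 * (p * np.log(2 * np.pi) + logdet + quad)


def _bare_expr(X):
    X = np.asarray(X, dtype=float)
    from .containers import ExpressionMatrix

    return ExpressionMatrix(
        X,
        gene_ids=[f"g{j}" for j in range(X.shape[1])],
        spot_ids=[f"s{i}" for i in range(X.shape[0])],
    )


# ---------------------------------------------------------------------------
# functional surface


def fit_pldr(source: LabeledSource, q: int, tol: float = 1e-6, max_iter: int = 100) -> FactorModel:
    """Fit the supervised factor model on labeled source data by EM."""
    est = PLDR(n_components=q, tol=tol, max_iter=max_iter)
    est.fit(source.expr.values, source.labels)
    return est._to_model()


def project_source(model: FactorModel, source: LabeledSource) -> Embedding:
    """Posterior mean latent scores E[u_i | x_i, z_i] under the fitted model."""
    if source.expr.p != model.p:
        raise ValueError(f"source has {source.expr.p} genes, model expects {model.p}")
    M = _posterior_means(
        source.expr.values, model.loading, model.resid_var,
        model.cluster_means, model.cluster_covs, source.labels,
    )
    return Embedding(M)


def pldr_loglik(model: FactorModel, source: LabeledSource) -> float:
    """Observed-data log-likelihood sum_i log N(x_i; W mu_{z_i}, W Sigma_{z_i} W' + Lambda)."""
    X = source.expr.values
    if X.shape[1] != model.p:
        raise ValueError("dimension mismatch between data and model")
    lam = model.resid_var
    Li = 1.0 / lam
    W = model.loading
    WtLi = W.T * Li[None, :]
    B = WtLi @ W
    ll = 0.0
    for k in range(model.n_clusters):
        idx = np.flatnonzero(source.labels == k + 1)
        if idx.size == 0:
            continue
        ll += _marginal_loglik_block(
            X[idx], W, lam, model.cluster_means[k], model.cluster_covs[k], Li, B
        )
    return float(ll)
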