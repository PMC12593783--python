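"""Step 2: adaptive transfer of the source loading to the target.

The target embedding V and loading W minimize

    sum_i || x_tgt,i - W v_i ||^2  +  lambda * || W - W0_hat ||_F^2,

solved by alternating exact least-squares updates with W initialized at
the transferred loading W0_hat.  The penalty weight lambda is chosen by
a two-fold reconstruction scheme: fit on one half, score the held-out
half by least squares, sum the cross-fold errors over both directions.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import Embedding, ExpressionMatrix, TransferConfig

__all__ = ["TransferFactorization", "transfer_objective", "als_fit", "select_lambda"]

_RIDGE = 1e-10
_MONOTONE_SLACK = 1e-8


def _values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def transfer_objective(X_tgt, W, V, lam: float, W0) -> float:
    """Penalized reconstruction objective ||X - V W'||_F^2 + lam ||W - W0||_F^2."""
    X = _values(X_tgt)
    W = np.asarray(W, dtype=float)
    W0 = np.asarray(W0, dtype=float)
    Vs = V.scores if isinstance(V, Embedding) else np.asarray(V, dtype=float)
    if W.shape != W0.shape or X.shape != (Vs.shape[0], W.shape[0]) or Vs.shape[1] != W.shape[1]:
        raise ValueError(
            f"shape mismatch: X{X.shape}, W{W.shape}, V{Vs.shape}, W0{W0.shape}"
        )
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    resid = X - Vs @ W.T
    dW = W - W0
    return float(np.sum(resid * resid) + lam * np.sum(dW * dW))


def _solve_scores(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Least-squares scores V = X W (W'W)^{-1}, ridged if near-singular."""
    G = W.T @ W
    try:
        cond = np.linalg.cond(G)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("W'W near-singular; adding 1e-10 ridge", stacklevel=2)
        G = G + _RIDGE * np.eye(G.shape[0])
    return np.linalg.solve(G, W.T @ X.T).T


def als_fit(X_tgt, W0, lam: float, config: TransferConfig | None = None):
    """Alternating least squares for the penalized factorization.

    Updates are the exact blockwise minimizers: V-step
    v_i = (W'W)^{-1} W' x_i, W-step W = (X'V + lam W0)(V'V + lam I)^{-1};
    W starts at W0 and the V-step runs first.  The objective is
    non-increasing across half-steps (checked, hard error otherwise).

    Returns
    -------
    (W, Embedding) : the fitted loading and target scores.
    """
    config = config or TransferConfig()
    X = _values(X_tgt)
    W0 = np.asarray(W0, dtype=float)
    p, q = W0.shape
    if q >= p:
        raise ValueError(f"q={q} must be smaller than p={p}")
    if X.shape[1] != p:
        raise ValueError(f"X has {X.shape[1]} genes, W0 expects {p}")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    W = W0.copy()
    Iq = np.eye(q)
    prev = np.inf
    trace: list[float] = []
    for _ in range(config.max_iter):
        V = _solve_scores(X, W)
        obj_v = transfer_objective(X, W, V, lam, W0)
        _check_decrease(prev, obj_v, trace)
        W = np.linalg.solve(V.T @ V + lam * Iq, V.T @ X + lam * W0.T).T
        obj_w = transfer_objective(X, W, V, lam, W0)
        _check_decrease(obj_v, obj_w, trace)
        if prev - obj_w < config.tol * (abs(obj_w) + 1.0):
            prev = obj_w
            break
        prev = obj_w
    V = _solve_scores(X, W)  # final scores consistent with the returned W
    return W, Embedding(V)


def _check_decrease(before: float, after: float, trace: list) -> None:
    if after > before + _MONOTONE_SLACK * max(1.0, abs(before)):
        raise RuntimeError(f"ALS objective increased from {before:.10g} to {after:.10g}")
    trace.append(after)


def select_lambda(X_tgt, W0, config: TransferConfig | None = None):
    """Two-fold reconstruction selection of the transfer penalty.

    Rows are split evenly into two folds by a seeded permutation.  For
    each grid value, the loading fit on one fold reconstructs the other
    fold through least-squares scores; errors from both directions are
    summed and the minimizing lambda is returned (ties go to the
    smaller value).
    """
    config = config or TransferConfig()
    X = _values(X_tgt)
    W0 = np.asarray(W0, dtype=float)
    n = X.shape[0]
    q = W0.shape[1]
    if n < 4:
        raise ValueError("need at least 4 target rows for two folds")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    folds = (perm[: n // 2], perm[n // 2:])
    if min(len(f) for f in folds) < q + 1:
        raise ValueError(f"fold smaller than q+1={q + 1}")
    grid = sorted(config.lambda_grid)
    errors = []
    for lam in grid:
        err = 0.0
        for train, test in ((folds[0], folds[1]), (folds[1], folds[0])):
            W_fit, _ = als_fit(X[train], W0, lam, config)
            V_test = _solve_scores(X[test], W_fit)
            resid = X[test] - V_test @ W_fit.T
            err += float(np.sum(resid * resid))
        errors.append(err)
    best = int(np.argmin(errors))  # argmin takes the first (smallest lambda) on ties
    return grid[best], dict(zip(grid, errors))


class TransferFactorization(BaseEstimator, TransformerMixin):
    """Penalized matrix factorization transferring a prior loading.

    Parameters
    ----------
    prior_loading : ndarray (p, q)
        The loading learned on the source (the ridge target W0).
    lam : float or "auto", default "auto"
        Penalty weight; "auto" selects it by two-fold reconstruction.
    lambda_grid : sequence of float
        Candidate penalties for the automatic selection.
    max_iter, tol : ALS controls.
    random_state : int
        Seed for the fold split.

    Attributes
    ----------
    loading_ : ndarray (p, q)
        Adapted target loading W.
    embedding_ : ndarray (n, q)
        Target scores V from the final full-data fit.
    lambda_ : float
        The penalty actually used.
    cv_errors_ : dict
        Per-lambda cross-fold reconstruction errors (empty if lam fixed).
    """

    def __init__(self, prior_loading=None, lam="auto",
                 lambda_grid=(0.0, 0.01, 0.1, 1.0, 10.0, 100.0),
                 max_iter=200, tol=1e-8, random_state=0):
        self.prior_loading = prior_loading
        self.lam = lam
        self.lambda_grid = lambda_grid
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _config(self) -> TransferConfig:
        return TransferConfig(lambda_grid=tuple(self.lambda_grid), max_iter=self.max_iter,
                              tol=self.tol, seed=self.random_state)

    def fit(self, X, y=None):
        if self.prior_loading is None:
            raise ValueError("prior_loading is required")
        X = check_array(X, dtype=np.float64)
        W0 = np.asarray(self.prior_loading, dtype=float)
        cfg = self._config()
        if self.lam == "auto":
            lam, errs = select_lambda(X, W0, cfg)
        else:
            lam, errs = float(self.lam), {}
        W, V = als_fit(X, W0, lam, cfg)
        self.loading_ = W
        self.embedding_ = V.scores
        self.lambda_ = lam
        self.cv_errors_ = errs
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "loading_")
        X = check_array(X, dtype=np.float64)
        return _solve_scores(X, self.loading_)
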