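"""End-to-end orchestration, clustering evaluation, and marker detection.

The full run chains the three stages: align source and target genes,
optionally preprocess both, fit the supervised factor model on the
source, adapt the loading to the target by penalized ALS (penalty
chosen by two-fold reconstruction), build the 5-nearest-neighbor spot
graph, and cluster the transferred embedding with the Potts-prior
spatial mixture (beta by line search; K fixed or by modified BIC).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import (
    Embedding,
    ExpressionMatrix,
    FactorModel,
    LabeledSource,
    SpatialCoords,
    TransferConfig,
)
from .io import align_genes, preprocess
from .pldr import fit_pldr
from .spgmm import (
    _DEFAULT_BETA_GRID,
    build_knn_graph,
    fit_spgmm,
    gaussian_classify_init,
    line_search_beta,
    select_K,
)
from .transfer import als_fit, select_lambda

__all__ = ["TransST", "run_transst", "adjusted_rand_index", "find_markers", "plot_spatial_labels"]


class TransST(BaseEstimator, ClusterMixin):
    """Transfer-learning spatial clustering of a target expression matrix.

    Parameters
    ----------
    n_components : int, default 15
        Latent dimension q shared by all three stages.
    n_clusters : int or "auto", default "auto"
        Number of clusters; "auto" selects over ``k_range`` by modified BIC.
    lambda_grid : sequence of float
        Candidate transfer penalties (two-fold reconstruction choice).
    beta : float or "auto"
        Potts smoothing weight; "auto" line-searches ``beta_grid``.
    n_neighbors : int, default 5
        Spot graph degree.
    do_preprocess : bool, default False
        Apply count normalization / HVG selection / scaling to both
        datasets before modeling (for raw-count inputs).
    n_hvg : int, default 2000
        Highly-variable-gene count when preprocessing.
    random_state : int
        Seed for fold splits and mixture initialization.

    Attributes
    ----------
    labels_ : ndarray of int, 1-based cluster assignments of target spots.
    embedding_ : ndarray (n, q), the transferred target representation.
    source_model_ : FactorModel from the supervised source fit.
    lambda_, beta_, n_clusters_ : selected hyperparameters.
    spatial_fit_ : SpatialFit with traces and criterion tables.
    manifest_ : dict of the run's seeds and selections.
    """

    def __init__(self, n_components=15, n_clusters="auto",
                 lambda_grid=(0.0, 0.01, 0.1, 1.0, 10.0, 100.0),
                 beta="auto", beta_grid=_DEFAULT_BETA_GRID, k_range=(2, 3, 4, 5, 6, 7),
                 n_neighbors=5, do_preprocess=False, n_hvg=2000,
                 pldr_tol=1e-6, pldr_max_iter=100, random_state=0):
        self.n_components = n_components
        self.n_clusters = n_clusters
        self.lambda_grid = lambda_grid
        self.beta = beta
        self.beta_grid = beta_grid
        self.k_range = k_range
        self.n_neighbors = n_neighbors
        self.do_preprocess = do_preprocess
        self.n_hvg = n_hvg
        self.pldr_tol = pldr_tol
        self.pldr_max_iter = pldr_max_iter
        self.random_state = random_state

    def fit(self, X, y=None, *, coords, source_X, source_y):
        """Fit on a target matrix given coordinates and a labeled source.

        ``X`` and ``source_X`` may be ExpressionMatrix objects (gene
        alignment applies) or plain arrays over an identical gene panel.
        """
        target = _as_expr(X, "t")
        source = _as_expr(source_X, "s")
        coords = coords if isinstance(coords, SpatialCoords) else SpatialCoords(coords)
        src = LabeledSource(source, np.asarray(source_y, dtype=int))
        fit, emb, model, manifest = run_transst(
            src, target, coords, q=self.n_components, K=self.n_clusters,
            lambda_grid=self.lambda_grid, beta=self.beta, beta_grid=self.beta_grid,
            k_range=self.k_range, n_neighbors=self.n_neighbors,
            do_preprocess=self.do_preprocess, n_hvg=self.n_hvg,
            pldr_tol=self.pldr_tol, pldr_max_iter=self.pldr_max_iter,
            seed=self.random_state,
        )
        self.spatial_fit_ = fit
        self.labels_ = fit.labels
        self.embedding_ = emb.scores
        self.source_model_ = model
        self.lambda_ = manifest["lambda"]
        self.beta_ = fit.beta
        self.n_clusters_ = fit.K
        self.manifest_ = manifest
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y=y, **kwargs).labels_


def _as_expr(X, prefix: str) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    X = np.asarray(X, dtype=float)
    return ExpressionMatrix(
        X,
        gene_ids=[f"g{j}" for j in range(X.shape[1])],
        spot_ids=[f"{prefix}{i}" for i in range(X.shape[0])],
    )


def run_transst(source: LabeledSource, target: ExpressionMatrix, coords: SpatialCoords,
                q: int, K="auto", *, lambda_grid=(0.0, 0.01, 0.1, 1.0, 10.0, 100.0),
                beta="auto", beta_grid=_DEFAULT_BETA_GRID, k_range=(2, 3, 4, 5, 6, 7),
                n_neighbors: int = 5, do_preprocess: bool = False, n_hvg: int = 2000,
                pldr_tol: float = 1e-6, pldr_max_iter: int = 100, seed: int = 0):
    """Run the three-stage pipeline; returns (SpatialFit, Embedding, FactorModel, manifest)."""
    if coords.n != target.n:
        raise ValueError("coordinates must align with target rows")
    try:
        src_expr, tgt_expr = align_genes(source.expr, target)
        if do_preprocess:
            n_hvg_eff = min(n_hvg, src_expr.p)
            src_expr = preprocess(src_expr, n_hvg=n_hvg_eff, do_scale=True)
            tgt_expr = preprocess(tgt_expr, n_hvg=n_hvg_eff, do_scale=True)
            src_expr, tgt_expr = align_genes(src_expr, tgt_expr)
        src = LabeledSource(src_expr, source.labels)
    except Exception as exc:
        raise RuntimeError(f"[stage: input preparation] {exc}") from exc

    try:
        model = fit_pldr(src, q=q, tol=pldr_tol, max_iter=pldr_max_iter)
    except Exception as exc:
        raise RuntimeError(f"[stage: pldr] {exc}") from exc

    try:
        X_tgt = tgt_expr.values - tgt_expr.values.mean(axis=0)  # centered for ALS
        tcfg = TransferConfig(lambda_grid=tuple(lambda_grid), seed=seed)
        lam, cv_errors = select_lambda(X_tgt, model.loading, tcfg)
        W, V = als_fit(X_tgt, model.loading, lam, tcfg)
    except Exception as exc:
        raise RuntimeError(f"[stage: transfer] {exc}") from exc

    try:
        graph = build_knn_graph(coords, n_neighbors)
        # The supervised source model knows the cluster structure; its
        # latent Gaussians classify the target embedding to give an
        # additional, transfer-informed initialization candidate.
        src_init = gaussian_classify_init(V, model.cluster_means, model.cluster_covs)
        extra = (src_init,) if src_init is not None else ()
        if K == "auto":
            fit = select_K(V, graph, k_range, seed=seed, beta_grid=beta_grid,
                           extra_inits=extra)
        elif beta == "auto":
            fit = line_search_beta(V, graph, int(K), grid=beta_grid, seed=seed,
                                   extra_inits=extra)
        else:
            fit = fit_spgmm(V, graph, int(K), float(beta), seed=seed,
                            extra_inits=extra)
    except Exception as exc:
        raise RuntimeError(f"[stage: spgmm] {exc}") from exc

    manifest = {
        "seed": seed,
        "q": q,
        "lambda": lam,
        "lambda_cv_errors": cv_errors,
        "beta": fit.beta,
        "K": fit.K,
        "criterion_value": fit.criterion_value,
        "criterion_table": fit.criterion_table,
        "n_neighbors": n_neighbors,
        "n_genes": src_expr.p,
    }
    return fit, V, model, manifest


def adjusted_rand_index(a, b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"partition lengths differ: {a.shape[0]} vs {b.shape[0]}")
    return float(adjusted_rand_score(a, b))


def find_markers(expr: ExpressionMatrix, labels, min_lfc: float = 0.25,
                 alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker detection per cluster.

    For each cluster every gene is tested against all other spots
    (two-sided rank-sum); p-values are Bonferroni-adjusted over the p
    genes within the cluster.  Genes with adjusted p below ``alpha``
    and log-fold-change (difference of within/without cluster means of
    the supplied values, which should be log-normalized) at least
    ``min_lfc`` are retained, sorted by adjusted p then descending
    fold change.

    Returns
    -------
    DataFrame with columns gene_id, cluster, log_fold_change,
    test_statistic, p_value, adjusted_p.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != expr.n:
        raise ValueError("labels length must match spots")
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least two clusters")
    for k in clusters:
        if (labels == k).sum() < 3:
            raise ValueError(f"cluster {k} has fewer than 3 spots")
    X = expr.values
    p = expr.p
    rows = []
    constant = np.ptp(X, axis=0) == 0
    for k in clusters:
        mask = labels == k
        xin, xout = X[mask], X[~mask]
        lfc = xin.mean(axis=0) - xout.mean(axis=0)
        res = stats.mannwhitneyu(xin, xout, alternative="two-sided", axis=0)
        stat = np.asarray(res.statistic, dtype=float)
        pval = np.asarray(res.pvalue, dtype=float)
        # constant genes carry no evidence either way
        stat[constant] = xin.shape[0] * xout.shape[0] / 2.0
        pval[constant] = 1.0
        adj = np.minimum(pval * p, 1.0)
        keep = (adj < alpha) & (lfc >= min_lfc)
        for j in np.flatnonzero(keep):
            rows.append((expr.gene_ids[j], int(k), float(lfc[j]), float(stat[j]),
                         float(pval[j]), float(adj[j])))
    table = pd.DataFrame(
        rows, columns=["gene_id", "cluster", "log_fold_change", "test_statistic",
                       "p_value", "adjusted_p"],
    )
    return (
        table.sort_values(["cluster", "adjusted_p", "log_fold_change"],
                          ascending=[True, True, False], kind="stable")
        .reset_index(drop=True)
    )


def plot_spatial_labels(coords: SpatialCoords, labels, path) -> None:
    """Minimal spatial heatmap of cluster labels, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = coords.coords if isinstance(coords, SpatialCoords) else np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=labels, cmap="tab10", s=8)
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
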