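"""Core data containers shared across the package.

The containers are deliberately lightweight: plain dataclasses around
numpy arrays, with validation at construction time.  Expression data is
always oriented spots-in-rows, genes-in-columns.  Cluster labels are
1-based everywhere a user sees them; row/column indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "SpatialCoords",
    "LabeledSource",
    "FactorModel",
    "Embedding",
    "NeighborGraph",
    "SpatialFit",
    "TransferConfig",
    "SimConfig",
    "SimulatedDataset",
]


def _as_str_array(ids, name: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=str)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(np.unique(arr)) != arr.size:
        dup = [x for x in arr if list(arr).count(x) > 1]
        raise ValueError(f"duplicate {name}: {sorted(set(dup))[:5]}")
    return arr


@dataclass
class ExpressionMatrix:
    """An n-spots × p-genes expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Expression values (raw counts or normalized); must be finite.
    gene_ids : array-like of str, length p
        Unique gene identifiers (column labels).
    spot_ids : array-like of str, length n
        Unique spot/cell identifiers (row labels).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("expression matrix must have at least one spot and one gene")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.spot_ids = _as_str_array(self.spot_ids, "spot_ids")
        if self.gene_ids.size != p:
            raise ValueError(f"gene_ids has {self.gene_ids.size} entries for {p} columns")
        if self.spot_ids.size != n:
            raise ValueError(f"spot_ids has {self.spot_ids.size} entries for {n} rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class SpatialCoords:
    """2-D spot coordinates, row-aligned with a target ExpressionMatrix."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an n×2 matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite entries")
        uniq = np.unique(self.coords, axis=0)
        self.has_duplicates = uniq.shape[0] < self.coords.shape[0]
        if self.has_duplicates:
            warnings.warn("duplicate spatial coordinates present", stacklevel=2)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class LabeledSource:
    """Source expression matrix plus 1-based cluster labels."""

    expr: ExpressionMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.all(as_int == self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        if self.labels.shape != (self.expr.n,):
            raise ValueError("labels length must match number of source rows")
        k = int(self.labels.max(initial=0))
        if self.labels.min(initial=1) < 1:
            raise ValueError("labels must be 1-based positive integers")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, k + 1)):
            raise ValueError(f"labels must cover 1..{k} with no gaps; found {present}")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


@dataclass
class FactorModel:
    """Fitted supervised factor model: shared loading, diagonal residual
    variance, and per-cluster latent Gaussian parameters."""

    loading: np.ndarray          # (p, q)
    resid_var: np.ndarray        # (p,) diagonal of the residual covariance
    cluster_means: np.ndarray    # (K, q)
    cluster_covs: np.ndarray     # (K, q, q) symmetric positive definite
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loading = np.asarray(self.loading, dtype=float)
        self.resid_var = np.asarray(self.resid_var, dtype=float)
        self.cluster_means = np.asarray(self.cluster_means, dtype=float)
        self.cluster_covs = np.asarray(self.cluster_covs, dtype=float)
        if self.loading.ndim != 2:
            raise ValueError("loading must be p×q")
        p, q = self.loading.shape
        if self.resid_var.shape != (p,) or np.any(self.resid_var <= 0):
            raise ValueError("resid_var must be length p and strictly positive")
        if self.cluster_means.ndim != 2 or self.cluster_means.shape[1] != q:
            raise ValueError("cluster_means must be K×q")
        K = self.cluster_means.shape[0]
        if self.cluster_covs.shape != (K, q, q):
            raise ValueError("cluster_covs must be K×q×q")
        for k in range(K):
            c = self.cluster_covs[k]
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"cluster covariance {k + 1} not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"cluster covariance {k + 1} not positive definite")

    @property
    def p(self) -> int:
        return self.loading.shape[0]

    @property
    def q(self) -> int:
        return self.loading.shape[1]

    @property
    def n_clusters(self) -> int:
        return self.cluster_means.shape[0]


@dataclass
class Embedding:
    """An n × q latent representation (rows aligned with its expression matrix)."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("embedding contains non-finite values")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def q(self) -> int:
        return self.scores.shape[1]


@dataclass
class NeighborGraph:
    """Directed k-nearest-neighbor lists over spot coordinates."""

    neighbors: np.ndarray  # (n, k) int indices, no self loops
    k: int

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        if self.neighbors.ndim != 2 or self.neighbors.shape[1] != self.k:
            raise ValueError("neighbors must be n×k")
        n = self.neighbors.shape[0]
        if np.any(self.neighbors < 0) or np.any(self.neighbors >= n):
            raise ValueError("neighbor indices out of range")
        if np.any(self.neighbors == np.arange(n)[:, None]):
            raise ValueError("self-loop in neighbor lists")

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]


@dataclass
class SpatialFit:
    """Result of the spatial Gaussian-mixture clustering step."""

    labels: np.ndarray             # (n,) in 1..K
    responsibilities: np.ndarray   # (n, K)
    cluster_means: np.ndarray      # (K, q)
    cluster_covs: np.ndarray       # (K, q, q)
    beta: float
    K: int
    weights: np.ndarray | None = None  # (K,) mixing proportions
    criterion_value: float = float("nan")
    pseudo_loglik_trace: list = field(default_factory=list)
    pseudo_loglik: float = float("nan")
    criterion_table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.responsibilities = np.asarray(self.responsibilities, dtype=float)
        if self.weights is None:
            self.weights = np.full(self.K, 1.0 / self.K)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.labels.shape[0]
        if self.responsibilities.shape != (n, self.K):
            raise ValueError("responsibilities must be n×K")
        rowsums = self.responsibilities.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-8):
            raise ValueError("responsibility rows must sum to 1")
        if not np.array_equal(self.labels, np.argmax(self.responsibilities, axis=1) + 1):
            raise ValueError("labels must be the argmax of responsibilities (1-based)")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")


@dataclass
class TransferConfig:
    """Settings for the penalized target factorization."""

    lambda_grid: tuple = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)
    max_iter: int = 200
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(v) for v in self.lambda_grid)
        if len(grid) == 0:
            raise ValueError("lambda_grid must be non-empty")
        if any(v < 0 for v in grid):
            raise ValueError("lambda values must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        self.lambda_grid = grid


@dataclass
class SimConfig:
    """Configuration of the synthetic data generator.

    Defaults define the benchmark conditions: a 50×50 lattice of spots,
    K=4 clusters from a mildly supercritical Potts field (beta_true=1.5
    gives smooth domains while keeping all clusters represented after
    the 100-sweep quench), q=5 latent dimensions, p=200 genes with a
    planted marker block (genes 1, 2, 3 and 4–10 uniquely marking
    clusters 1–4), unit target noise e, and an i.i.d. labeled source of
    n_source cells.  The marker loading scale (0.7) places the three
    weak marker dimensions near the unsupervised detection threshold at
    unit noise — the low-SNR regime that external labels are meant to
    rescue.
    """

    grid_height: int = 50
    grid_width: int = 50
    K: int = 4
    beta_true: float = 1.5
    q: int = 5
    p: int = 200
    noise_e: float = 1.0
    noise_e_source: float = 1.0
    n_source: int = 2500
    seed: int = 0
    marker_map: tuple = ((1,), (2,), (3,), (4, 5, 6, 7, 8, 9, 10))  # 1-based gene ids per cluster
    latent_mean_scale: float = 3.0
    marker_scale: float = 0.7
    n_sweeps: int = 100

    def __post_init__(self) -> None:
        if self.grid_height < 2 or self.grid_width < 2:
            raise ValueError("lattice must be at least 2×2")
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.beta_true < 0 or self.noise_e < 0 or self.noise_e_source < 0:
            raise ValueError("beta_true and noise scales must be nonnegative")
        if len(self.marker_map) != self.K:
            raise ValueError("marker_map must assign genes to each of the K clusters")
        flat = [g for genes in self.marker_map for g in genes]
        if len(set(flat)) != len(flat):
            raise ValueError("marker genes must be distinct")
        if flat and max(flat) > self.p:
            raise ValueError("p too small for the marker map")
        if self.q <= self.K:
            raise ValueError("q must exceed K so non-marker genes have cluster-neutral dims")

    @property
    def n_target(self) -> int:
        return self.grid_height * self.grid_width


@dataclass
class SimulatedDataset:
    """A paired source/target draw from the generative model."""

    target_expr: ExpressionMatrix
    coords: SpatialCoords
    true_labels: np.ndarray
    source: LabeledSource
    true_loading: np.ndarray
    true_means: np.ndarray
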