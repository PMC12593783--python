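"""Synthetic data generator: Potts label fields with a linear factor emission.

The generative process mirrors the validation design: cluster labels on
a rectangular lattice are drawn from a K-state Potts model by Gibbs
sampling; each spot then receives a q-dimensional latent factor
u_i ~ N(mu_{z_i}, I) with well-separated cluster means; expression is
the projection X = U W' through a planted loading matrix, plus
e * N(0, 1) noise on the target.

Marker structure: latent dimensions 1..K are cluster-informative
(mu_k = latent_mean_scale * e_k) and only the marker genes load on
them — genes 1, 2, 3 on dimensions 1-3 and genes 4-10 on dimension 4
under the defaults — so those genes uniquely mark clusters 1..4.  All
remaining genes carry dense N(0, 1) loadings on the cluster-neutral
dimensions K+1..q and are therefore not differentially expressed.

The labeled source is drawn i.i.d. from the same cluster-conditional
factor model (no spatial field), with its own noise scale.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    ExpressionMatrix,
    LabeledSource,
    SimConfig,
    SimulatedDataset,
    SpatialCoords,
)

__all__ = ["sample_potts_labels", "generate_factor_data", "add_noise", "simulate_dataset"]


def sample_potts_labels(config: SimConfig):
    """Sample a K-state Potts label field on the lattice by Gibbs sampling.

    Single-site conditionals p(z_i = k | rest) ∝ exp(beta_true * #{rook
    neighbors with label k}) are updated in checkerboard (even/odd
    parity) blocks — a valid Gibbs schedule on the bipartite lattice —
    for ``config.n_sweeps`` full sweeps from a uniform random start.
    Deterministic given ``config.seed``.

    Returns
    -------
    (labels, coords) : 1-based labels of length H*W (row-major) and the
    integer lattice coordinates as SpatialCoords.
    """
    H, W, K = config.grid_height, config.grid_width, config.K
    rng = np.random.default_rng([config.seed, 0])
    field = rng.integers(0, K, size=(H, W))
    beta = config.beta_true
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    parity = (rr + cc) % 2
    if beta > 0:
        for _ in range(config.n_sweeps):
            for par in (0, 1):
                counts = _neighbor_counts(field, K)
                logits = beta * counts
                logits -= logits.max(axis=-1, keepdims=True)
                probs = np.exp(logits)
                probs /= probs.sum(axis=-1, keepdims=True)
                u = rng.random(size=(H, W, 1))
                draw = (probs.cumsum(axis=-1) < u).sum(axis=-1)
                mask = parity == par
                field[mask] = draw[mask]
    coords = np.column_stack([cc.ravel().astype(float), rr.ravel().astype(float)])
    return field.ravel() + 1, SpatialCoords(coords)


def _neighbor_counts(field: np.ndarray, K: int) -> np.ndarray:
    """Per-site count of rook neighbors holding each label (edges unpadded)."""
    H, W = field.shape
    counts = np.zeros((H, W, K))
    onehot = np.zeros((H, W, K))
    onehot[np.arange(H)[:, None], np.arange(W)[None, :], field] = 1.0
    counts[1:, :, :] += onehot[:-1, :, :]
    counts[:-1, :, :] += onehot[1:, :, :]
    counts[:, 1:, :] += onehot[:, :-1, :]
    counts[:, :-1, :] += onehot[:, 1:, :]
    return counts


def _build_loading(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    p, q, K = config.p, config.q, config.K
    W = np.zeros((p, q))
    for k, genes in enumerate(config.marker_map):
        for g in genes:
            W[g - 1, k] = config.marker_scale
    marker_rows = {g - 1 for genes in config.marker_map for g in genes}
    background = np.array(sorted(set(range(p)) - marker_rows))
    if background.size:
        W[np.ix_(background, np.arange(K, q))] = rng.standard_normal(
            (background.size, q - K)
        )
    return W


def generate_factor_data(labels: np.ndarray, config: SimConfig) -> "SimulatedDataset":
    """Emit noiseless target expression and a noisy i.i.d. labeled source.

    Latent factors are u_i ~ N(mu_{z_i}, I); the target matrix U W' has
    rank at most q.  Target noise is added separately (``add_noise``).
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng([config.seed, 1])
    K, q, p = config.K, config.q, config.p
    mus = np.zeros((K, q))
    mus[np.arange(K), np.arange(K)] = config.latent_mean_scale
    W = _build_loading(config, rng)

    n0 = labels.shape[0]
    U_tgt = mus[labels - 1] + rng.standard_normal((n0, q))
    X_tgt = U_tgt @ W.T

    n1 = config.n_source
    src_labels = rng.integers(1, K + 1, size=n1)
    U_src = mus[src_labels - 1] + rng.standard_normal((n1, q))
    X_src = U_src @ W.T
    if config.noise_e_source > 0:
        X_src = X_src + config.noise_e_source * rng.standard_normal(X_src.shape)

    genes = np.array([f"gene{j + 1}" for j in range(p)])
    target = ExpressionMatrix(X_tgt, genes, np.array([f"spot{i}" for i in range(n0)]))
    source = LabeledSource(
        ExpressionMatrix(X_src, genes, np.array([f"cell{i}" for i in range(n1)])),
        src_labels,
    )
    # coords belong to the label field; caller pairs them (simulate_dataset
    # does); the placeholder is a degenerate line of distinct points
    return SimulatedDataset(
        target_expr=target,
        coords=SpatialCoords(np.column_stack([np.arange(n0, dtype=float), np.zeros(n0)])),
        true_labels=labels,
        source=source,
        true_loading=W,
        true_means=mus,
    )


def add_noise(expr: ExpressionMatrix, e: float, seed: int) -> ExpressionMatrix:
    """Return expr + e * Z with Z i.i.d. standard normal (bitwise copy at e=0)."""
    if e < 0:
        raise ValueError("noise scale must be nonnegative")
    if e == 0:
        return ExpressionMatrix(expr.values.copy(), expr.gene_ids, expr.spot_ids)
    rng = np.random.default_rng([seed, 2])
    noisy = expr.values + e * rng.standard_normal(expr.values.shape)
    return ExpressionMatrix(noisy, expr.gene_ids, expr.spot_ids)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full draw: Potts labels -> factor emission -> target noise."""
    labels, coords = sample_potts_labels(config)
    data = generate_factor_data(labels, config)
    data.coords = coords
    data.target_expr = add_noise(data.target_expr, config.noise_e, config.seed)
    return data
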