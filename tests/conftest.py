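"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from transst.containers import ExpressionMatrix, SimConfig
from transst.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A 20×20-lattice benchmark draw (400 spots, 50 genes, 400 source cells)."""
    cfg = SimConfig(grid_height=20, grid_width=20, p=50, n_source=400, seed=7)
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        gene_ids=[f"{prefix}{j}" for j in range(values.shape[1])],
        spot_ids=[f"s{i}" for i in range(values.shape[0])],
    )


@pytest.fixture()
def expr_factory():
    return make_expr
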