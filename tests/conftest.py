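import numpy as np
import pandas as pd
import pytest

from airhealth.io import AdjacencySpec, GridCovariates, RunConfig
from airhealth.synthetic import make_lattice


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def path_adjacency():
    """2-3 node path graph (chain), handy for exact Leroux checks."""
    return AdjacencySpec(n_areas=3, edges=frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def small_lattice():
    return make_lattice(3, 3)


@pytest.fixture
def short_config():
    """A config short enough for unit-test MCMC runs."""
    return RunConfig(
        n_iterations=600, n_burnin=200, thin_for_predictions=1, h=50, seed=7
    )


def make_grid(q=2, n_side=4, T=2, seed=0):
    """Small deterministic grid-covariates table."""
    rng = np.random.default_rng(seed)
    n = n_side * n_side
    gx, gy = np.meshgrid(
        (np.arange(n_side) + 0.5) / n_side, (np.arange(n_side) + 0.5) / n_side
    )
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    modelled = 10.0 + 5.0 * rng.random((q, n, T))
    temperature = 8.0 + 2.0 * coords[:, 1][:, None] + 0.1 * np.arange(T)[None, :]
    return GridCovariates(
        points=pd.DataFrame(
            {
                "point_id": np.arange(n),
                "x": coords[:, 0],
                "y": coords[:, 1],
                "site_type": np.where(coords[:, 0] < 0.5, "urban background", "rural"),
            }
        ),
        years=np.arange(T),
        pollutants=[f"pol{j + 1}" for j in range(q)],
        modelled=modelled,
        temperature=temperature,
    )


@pytest.fixture
def tiny_grid():
    return make_grid()
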