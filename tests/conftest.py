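import numpy as np
import pytest

from localuse import (
    DGPConfig,
    LandscapeConfig,
    gen_landscape,
    knn_weights,
    weighted_centroids,
)


@pytest.fixture(scope="session")
def small_landscape():
    """16-unit landscape on a 16 km grid (100-section lattice)."""
    return gen_landscape(LandscapeConfig(n_units=16, grid_extent_km=16.0, seed=11))


@pytest.fixture(scope="session")
def medium_weights():
    """kNN weights on 100 random centroids (asymmetric in general)."""
    rng = np.random.default_rng(5)
    coords = rng.uniform(0, 40, (100, 2))
    return knn_weights(coords, k=3)


@pytest.fixture(scope="session")
def small_weights(small_landscape):
    cents = weighted_centroids(small_landscape.blocks)
    return knn_weights(
        cents[["cx_km", "cy_km"]].to_numpy(), k=3, ids=cents["unit_id"].to_numpy()
    )


@pytest.fixture
def simple_dgp():
    return DGPConfig(
        rho=0.4,
        beta=np.array([1.0, 0.5]),
        theta=np.array([0.5, -0.3]),
        sigma=0.1,
        moe_scale=np.array([0.05, 0.05]),
    )
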