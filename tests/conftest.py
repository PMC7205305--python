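import numpy as np
import pandas as pd
import pytest

import gravmig as gm


@pytest.fixture(scope="session")
def small_landscape():
    """4 coarse x 5 fine synthetic landscape (20 units), fixed seed."""
    cfg = gm.LandscapeConfig(n_coarse=4, fine_per_coarse=5, seed=11)
    units, adj, dist = gm.generate_landscape(cfg)
    return units, adj, dist


@pytest.fixture(scope="session")
def small_observation(small_landscape):
    units, adj, dist = small_landscape
    flows, truth = gm.simulate_flows(units, adj, dist, sampling_fraction=0.1, seed=13)
    return flows, truth


@pytest.fixture(scope="session")
def fitted_small_model(small_landscape, small_observation):
    """A short but real multi-chain fit on the small landscape, shared across
    tests that only inspect fitted state."""
    units, adj, dist = small_landscape
    flows, _ = small_observation
    model = gm.GravityMigrationModel(n_chains=3, n_steps=4000, thin=5, seed=17)
    return model.fit(units, flows, adjacency=adj, distances=dist)


@pytest.fixture
def toy_units():
    """Hand-written 3-unit table spanning two coarse units."""
    return pd.DataFrame({
        "id": ["a", "b", "c"],
        "coarse_id": ["X", "X", "Y"],
        "population": [100.0, 300.0, 200.0],
        "urban_prop": [0.2, 0.8, 0.5],
        "gcp_pc": [3.0, 6.0, 4.0],
        "cx": [0.0, 3.0, 0.0],
        "cy": [0.0, 4.0, 10.0],
    })


def random_unit_table(rng: np.random.Generator, n_coarse: int, fine_per: int) -> pd.DataFrame:
    n = n_coarse * fine_per
    return pd.DataFrame({
        "id": [f"u{k}" for k in range(n)],
        "coarse_id": [f"C{k // fine_per}" for k in range(n)],
        "population": rng.lognormal(9.0, 1.0, n),
        "urban_prop": rng.uniform(0, 1, n),
        "gcp_pc": rng.lognormal(1.5, 0.5, n),
        "cx": rng.uniform(0, 100, n),
        "cy": rng.uniform(0, 100, n),
    })
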