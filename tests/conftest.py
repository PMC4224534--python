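import numpy as np
import pandas as pd
import pytest

import fastslow as fs
from fastslow.trait_io import TRAIT_NAMES


@pytest.fixture(scope="session")
def small_config():
    """12-species pool config used for tree/oracle fixtures."""
    return fs.SimulationConfig(
        n_species=12, n_superclasses=2, n_classes=2, n_orders=3,
        n_families=4, n_genera=6, n_imputed_flags=0,
    )


@pytest.fixture(scope="session")
def small_pool(small_config):
    pool, truth = fs.simulate_species_pool(small_config, 42)
    return pool, truth


@pytest.fixture(scope="session")
def small_tree(small_pool):
    pool, _ = small_pool
    return fs.build_taxonomy_tree(pool.meta)


@pytest.fixture(scope="session")
def default_pool():
    """Default 76-species pool (the canonical study conditions)."""
    pool, truth = fs.simulate_species_pool(fs.SimulationConfig(), 1)
    return pool, truth


@pytest.fixture(scope="session")
def default_ranks(default_pool):
    pool, _ = default_pool
    return fs.fast_slow_ranks(fs.transform_traits(pool))


@pytest.fixture(scope="session")
def default_tree(default_pool):
    pool, _ = default_pool
    return fs.build_taxonomy_tree(pool.meta)


@pytest.fixture()
def tiny_traits_csv(tmp_path):
    """Well-formed 3-species traits CSV."""
    df = pd.DataFrame(
        {
            "species_id": ["a", "b", "c"],
            "longevity": [10.0, 20.0, 5.0],
            "age_maturity": [3.0, 8.0, 2.0],
            "max_length": [50.0, 120.0, 30.0],
            "length_maturity": [30.0, 80.0, 20.0],
            "fecundity": [1e4, 1e5, 1e3],
            "offspring_size": [1.5, 3.0, 1.0],
            "imputed": ["", "longevity;fecundity", ""],
        }
    )
    path = tmp_path / "traits.csv"
    df.to_csv(path, index=False)
    return path


def make_standardized(values, trait_names=None):
    """Wrap a raw matrix as a StandardizedTraitMatrix after z-scoring columns."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    z = (values - values.mean(0)) / values.std(0, ddof=1)
    return fs.StandardizedTraitMatrix(
        species_ids=[f"s{i}" for i in range(n)],
        trait_names=list(trait_names or [f"t{j}" for j in range(p)]),
        values=z,
        column_means=values.mean(0),
        column_sds=values.std(0, ddof=1),
    )
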