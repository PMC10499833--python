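import numpy as np
import pandas as pd
import pytest

from paimpact import SimulationConfig, generate_landscape, protection_table
from paimpact import io as pio


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_sites=80, n_species=12, n_years=8, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    sites, pas = generate_landscape(small_config)
    return sites, pas


@pytest.fixture(scope="session")
def small_protection(small_landscape):
    sites, pas = small_landscape
    return protection_table(sites, pas)


@pytest.fixture(scope="session")
def small_site_frame(small_landscape, small_protection):
    sites, _ = small_landscape
    return pio.sites_frame(sites).merge(
        small_protection[["site_id", "protected"]], on="site_id"
    )


def bm_trait(newick: str, seed: int) -> pd.Series:
    """Brownian-motion trait on a tree: the oracle for signal statistics."""
    from paimpact import tree_vcv

    V, labels = tree_vcv(newick)
    rng = np.random.default_rng(seed)
    x = np.linalg.cholesky(V + 1e-10 * np.eye(len(V))) @ rng.standard_normal(len(V))
    return pd.Series(x, index=labels)
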