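import numpy as np
import pandas as pd
import pytest

from dietscale import SimConfig
from dietscale.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated dataset shared by integration-style tests."""
    cfg = SimConfig(n_communities=8, species_pool_size=30, mean_richness=15, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """A study-scale simulated dataset (23 communities)."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def toy_samples():
    """Hand-built isotope samples across three communities."""
    rows = [
        # community, species, d13C values chosen on the enamel scale
        ("AAAA", "Alpha one", [4.1, -12.5]),
        ("AAAA", "Beta two", [-4.2]),
        ("BBBB", "Alpha one", [4.1, 4.1, 4.1]),
        ("BBBB", "Gamma three", [-12.5, -12.5]),
        ("CCCC", "Gamma three", [-12.5]),  # pure browser community
    ]
    recs = []
    i = 0
    for comm, sp, deltas in rows:
        for d in deltas:
            recs.append((f"s{i}", sp, comm, d))
            i += 1
    return pd.DataFrame(recs, columns=["sample_id", "species", "community", "d13C_enamel"])


def beta_draw(rng, mu, phi):
    """Helper: Beta(mu*phi, (1-mu)*phi) draws clipped inside (0,1)."""
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    return np.clip(y, 1e-6, 1 - 1e-6)
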