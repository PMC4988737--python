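import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twinlag as tl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dep_ace():
    """Time-1 depression generating values (a2=.26, c2=.14, e2=.60)."""
    return tl.ace_preset("depression")


@pytest.fixture(scope="session")
def paranoia_bivariate():
    """(depression, paranoia, latent correlations) generating preset."""
    return tl.bivariate_preset("paranoia")


@pytest.fixture(scope="session")
def paranoia_crosslag():
    return tl.crosslag_preset("paranoia")


@pytest.fixture(scope="session")
def cogdis_crosslag():
    return tl.crosslag_preset("cognitive_disorganization")


@pytest.fixture(scope="session")
def small_crosslag_data(paranoia_crosslag):
    """2000 pairs, two waves, 50% follow-up: quick but structured."""
    design = tl.SimDesign(n_mz=800, n_dz=1200, t2_retention=0.5, seed=42)
    return tl.simulate_twin_pairs(paranoia_crosslag, design)


@pytest.fixture(scope="session")
def univariate_fit(dep_ace):
    """A univariate dataset plus its fitted model, reused across tests."""
    design = tl.SimDesign(n_mz=2000, n_dz=2000, seed=5)
    data = tl.simulate_univariate(dep_ace, design)
    model = tl.UnivariateACE(data, "depression")
    return data, model, model.fit(seed=1)


def random_shares(rng, floor=0.05):
    x = rng.dirichlet([2.0, 2.0, 2.0])
    x = np.maximum(x, floor)
    return tuple(x / x.sum())
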