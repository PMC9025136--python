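import numpy as np
import pytest
from hypothesis import settings

from xopop import simdata

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_population():
    """A modest two-chromosome F1 population with 10% missing calls."""
    config = simdata.SimConfig(
        n_progeny=200,
        chromosomes=[("Chr01", 10_000_000, 1.3, 1.0), ("Chr02", 8_000_000, 1.0, 0.8)],
        nu_female=1.0,
        nu_male=1.0,
        missing_rate=0.10,
        seed=20_240_501,
    )
    return simdata.simulate_population(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(987_654_321)
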