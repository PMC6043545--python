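import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tunadrivers.effort import load_rules

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from tunadrivers.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def small_config():
    """A compact study: 4 stocks spanning 4 regions, 6 years."""
    return SyntheticConfig(
        n_years=6,
        start_year=2009,
        stocks=["WCPOSKJ", "IOYFT", "AOEBFT", "EPOBET"],
        grid_cells=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def study_scale_bundle():
    """Default study conditions: 19 stocks x 23 years, 48 fleets."""
    return generate_bundle(SyntheticConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_design(rng):
    """Well-conditioned 40 x 4 design with a known linear response."""
    x = rng.normal(size=(40, 4))
    beta = np.array([1.5, -2.0, 0.5, 0.0])
    y = 0.7 + x @ beta + rng.normal(0, 0.1, 40)
    return pd.DataFrame(x, columns=list("abcd")), y, beta
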