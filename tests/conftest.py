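import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import finitek as fk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_universe():
    """~360 jittered parcels with clustered marks and 40 risk-driven cases."""
    cfg = fk.SyntheticConfig(grid_nx=20, grid_ny=20, spacing=50.0, jitter_sd=3.0,
                             removal_fraction=0.1, field_range=200.0, q=40,
                             risk_slope=0.5, seed=42)
    locations, cases, flags = fk.generate_dataset(cfg)
    return cfg, locations, cases, flags


@pytest.fixture(scope="session")
def desk_universe():
    """The desk-scale study universe: ~1,800 parcels, clustered marks, q=100."""
    cfg = fk.SyntheticConfig(seed=11)
    locations, cases, flags = fk.generate_dataset(cfg)
    return cfg, locations, cases, flags


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
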