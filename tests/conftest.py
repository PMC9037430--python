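import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lumidip as ld

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_config() -> ld.SimulationConfig:
    return ld.SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def noise_free_plate():
    """Default plate with noise switched off (and its ground truth)."""
    cfg = ld.SimulationConfig(seed=3, cv=0.0, imaged_fraction=1.0)
    dataset, truth = ld.simulate_plate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def noisy_plate(default_config):
    dataset, truth = ld.simulate_plate(default_config)
    return default_config, dataset, truth


def make_series(times, rlu, counts=None, **kw):
    defaults = dict(cell_line="CL", drug="drugX", concentration=1e-8, replicate=1)
    defaults.update(kw)
    return ld.WellTimeSeries(
        times=np.asarray(times, float), rlu=np.asarray(rlu, float),
        counts=None if counts is None else np.asarray(counts, float), **defaults
    )


@pytest.fixture
def series_factory():
    return make_series
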