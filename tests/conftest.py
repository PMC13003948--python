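import logging

import numpy as np
import pytest

from forage_overlap.pipeline import run_pipeline
from forage_overlap.simulate import SimConfig, simulate_colony

logging.getLogger("forage_overlap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced colony for fast unit tests (3 + 4 birds, short deployments)."""
    return SimConfig(
        n_birds_autumn=3, n_birds_spring=4,
        deployment_days_min=1, deployment_days_max=3,
        trip_duration_median_h=8.0, rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_colony(small_config):
    return simulate_colony(small_config)


@pytest.fixture(scope="session")
def default_pipeline():
    """The full default synthetic colony run once through the whole pipeline."""
    return run_pipeline(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
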