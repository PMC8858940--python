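import numpy as np
import pytest

import tabata_ee as t


@pytest.fixture(scope="session")
def default_config():
    return t.SimulationConfig()


@pytest.fixture(scope="session")
def classic_plan(default_config):
    return t.build_window_plan(default_config.protocol)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Six subjects, reference site only — enough for feature/metric tests."""
    return t.simulate_cohort(default_config, 6, seed=42,
                             sites=["right_ankle"])


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return t.cohort_features(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
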