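import numpy as np
import pytest

from dediff import recovery, simulate
from dediff.design import build_hierarchy
from dediff.pipeline import analyze_subject


@pytest.fixture(scope="session")
def hierarchy():
    return build_hierarchy()


@pytest.fixture(scope="session")
def small_setup():
    """Reduced-grid config, grid and toy regions shared across tests."""
    return recovery.reduced_setup()


@pytest.fixture(scope="session")
def young_subject(small_setup):
    config, grid, regions = small_setup
    return simulate.simulate_subject(
        "sub-01", simulate.young_preset(), grid=grid, regions=regions,
        seed=11, n_volumes=config.n_volumes,
    )


@pytest.fixture(scope="session")
def young_analysis(small_setup, young_subject):
    config, grid, regions = small_setup
    s = young_subject
    return analyze_subject(
        s.study_runs, s.test_runs, s.study_events, s.test_events,
        grid, regions, config=config, subject="sub-01", group="young",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def noiseless_noise_model():
    return simulate.NoiseModel(sd=0.0, ar1_rho=0.0, drift_amplitude=0.0,
                               n_drift=0, baseline=100.0)
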