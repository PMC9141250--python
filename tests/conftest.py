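import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

import peachspec as ps


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size study: coarse 101-point grid, 30 fruit, 20/10
    split.  Keeps every pipeline stage exercised at unit-test cost."""
    return ps.RunConfig(
        synth=ps.SynthConfig(
            n_fruit=30,
            n_calibration=20,
            n_validation=10,
            grid_start_nm=560.0,
            grid_stop_nm=1060.0,
            grid_step_nm=5.0,
            seed=42,
        ),
        lo_nm=650.0,
        hi_nm=1030.0,
        spa_m_max=8,
        cars_n_runs=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ps.generate_dataset(small_config.synth)


@pytest.fixture(scope="session")
def default_o1_dataset():
    """One default-condition dataset (orientation O1 only)."""
    cfg = ps.SynthConfig(seed=7)
    return ps.generate_dataset(cfg, orientations=[ps.Orientation.O1])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
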