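import dataclasses

import numpy as np
import pytest

from spastimu import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Fully deterministic generator: no sensor noise, no kinematic jitter."""
    return dataclasses.replace(
        SimulationConfig(),
        accel_noise_sd_g=0.0,
        gyro_noise_sd_dps=0.0,
        rom_jitter_frac=0.0,
        catch_angle_jitter=0.0,
        catch_depth_jitter=0.0,
        cycle_jitter_frac=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort(config):
    return simulate_cohort({0: 2, 1: 2, 3: 2}, config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
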