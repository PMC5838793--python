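import numpy as np
import pytest
from hypothesis import settings

from ptrkit.library import load_compound_library
from ptrkit.synthetic import (DiffusionConfig, RampConfig,
                              default_transmission_curve,
                              simulate_diffusion_run, simulate_ramp_run)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture(scope="session")
def transmission_curve():
    return default_transmission_curve()


@pytest.fixture(scope="session")
def noiseless_ramp():
    """Default decanal/NO+ spike-and-ramp run without counting noise."""
    cfg = RampConfig(seed=0, noise=False)
    return cfg, simulate_ramp_run(cfg)


@pytest.fixture(scope="session")
def noisy_ramp():
    cfg = RampConfig(seed=42, noise=True)
    return cfg, simulate_ramp_run(cfg)


@pytest.fixture(scope="session")
def noiseless_diffusion():
    cfg = DiffusionConfig(seed=1, noise=False, block_duration_s=60.0)
    table, record = simulate_diffusion_run(cfg)
    return cfg, table, record


@pytest.fixture(scope="session")
def noisy_diffusion():
    cfg = DiffusionConfig(seed=7, noise=True, block_duration_s=60.0)
    table, record = simulate_diffusion_run(cfg)
    return cfg, table, record
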