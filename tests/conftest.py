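import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def clean_stack():
    """Noise-free, PSF-free 2-nucleus stack with aligned truth."""
    from centroquant.simulate import StackSimConfig, simulate_if_stack

    cfg = StackSimConfig(
        shape=(26, 160, 160), n_nuclei=2, psf_sigma_um=(0.0, 0.0),
        poisson_gain=0.0, read_sigma=0.0, texture_amp=0.0, seed=11,
    )
    return simulate_if_stack(cfg)


@pytest.fixture(scope="session")
def noisy_stack():
    """Single-nucleus stack under the generator's default noise model."""
    from centroquant.simulate import StackSimConfig, simulate_if_stack

    cfg = StackSimConfig(shape=(24, 96, 96), n_nuclei=1, seed=7)
    return simulate_if_stack(cfg)
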