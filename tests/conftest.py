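import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from semg.synthetic import NoiseConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def quick_cfg():
    """Noise config for fast desk-scale recordings (1 s rest + 1 s action)."""
    return NoiseConfig(snr_db=15.0, seed=7)


@pytest.fixture(scope="session")
def burst_recording(quick_cfg):
    """One 2 s recording with a known activation envelope."""
    return generate_recording(1, 2.0, 1000.0, quick_cfg)
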