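import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from respgate.synthetic import (
    BreathingParams,
    VelocityPhantomParams,
    generate_breathing_waveform,
    generate_profile_stream,
    generate_velocity_phantom,
)

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def short_breathing():
    """60 s ground-truth waveform with cycle annotations (fast fixture)."""
    params = BreathingParams(duration=60.0)
    signal, annotations = generate_breathing_waveform(params, seed=0)
    return params, signal, annotations


@pytest.fixture(scope="session")
def noiseless_stream(short_breathing):
    _, signal, _ = short_breathing
    return generate_profile_stream(signal, snr=np.inf)


@pytest.fixture(scope="session")
def phantom_pair():
    """Default paired velocity phantom with analytic ground truth."""
    params = VelocityPhantomParams()
    field_a, field_b, mask, truth = generate_velocity_phantom(params, seed=0)
    return params, field_a, field_b, mask, truth
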