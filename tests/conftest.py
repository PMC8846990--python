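import numpy as np
import pytest

from pulsentropy import EntropyParams, generate_pulse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return EntropyParams()


@pytest.fixture
def clean_pulse():
    """A noise-free, drift-free, jitter-free (exactly periodic) pulse."""
    return generate_pulse(
        duration_s=10.0, rr_jitter_sd=0.0, noise_sd=0.0, drift_amp=0.0, seed=1
    )


@pytest.fixture
def realistic_pulse():
    """A pulse with default jitter, noise and baseline wander."""
    return generate_pulse(duration_s=10.0, seed=42)
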