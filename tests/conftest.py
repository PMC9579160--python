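import numpy as np
import pytest

from smlight import synthetic as syn


@pytest.fixture()
def fast_bleach_config() -> syn.TraceConfig:
    """Short single-colour trace config for quick step-detection tests."""
    return syn.TraceConfig(
        n_frames=300,
        donor_brightness=300.0,
        background_mean=0.0,
        noise_sd=100.0,
        donor_bleach_rate=0.2,
        acceptor_bleach_rate=0.0,
    )


@pytest.fixture()
def noiseless_fret_config() -> syn.TraceConfig:
    return syn.TraceConfig(
        n_frames=50,
        noise_sd=0.0,
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
        state_sd=0.0,
        state_mean=63.0,
        donor_brightness=1000.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
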