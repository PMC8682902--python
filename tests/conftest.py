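import numpy as np
import pytest

from hepatobase import synthetic


@pytest.fixture(scope="session")
def default_phantom():
    """Default 96^3 liver phantom + labels, built once per session."""
    params = synthetic.PhantomParams(seed=42)
    volume, labels = synthetic.generate_liver_phantom(params)
    return params, volume, labels


@pytest.fixture(scope="session")
def clean_trace():
    """Noise-free pulsatile trace at the bundled rat-1 truth values."""
    params = synthetic.WaveformSimParams(
        hr=331.5, psv_true=864.37, edv_true=424.33, noise_sd=0.0, seed=0
    )
    return params, synthetic.simulate_velocity_trace(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
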