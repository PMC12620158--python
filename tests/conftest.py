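import pytest

from mrsiquant.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free default phantom (calibrated WM, no lesion), seed 1."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default phantom with 1% multiplicative amplitude noise, seed 2."""
    return generate_phantom(PhantomConfig(seed=2, noise_sigma=0.01))
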