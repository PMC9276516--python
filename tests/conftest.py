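import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def noisy_phantom():
    """A reproducible 64x64 three-class phantom with moderate noise."""
    from fcmseg.phantom import PhantomSpec, generate_phantom

    return generate_phantom(
        PhantomSpec(shape=(64, 64), class_sigma=0.05, seed=7)
    )


@pytest.fixture
def clean_phantom():
    """A noiseless 64x64 three-class phantom (analytically separable)."""
    from fcmseg.phantom import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(shape=(64, 64), class_sigma=0.0, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
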