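import numpy as np
import pytest

from btfsc.phantom import PhantomSpec, generate_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_pair():
    """One seeded 128x128 phantom pair at sigma=0.05 plus its clean twin."""
    noisy = generate_phantom_pair(PhantomSpec(seed=42, noise_sigma=0.05))
    clean = generate_phantom_pair(PhantomSpec(seed=42, noise_sigma=0.0))
    return noisy, clean


@pytest.fixture(scope="session")
def clean_benign():
    return generate_phantom_pair(
        PhantomSpec(seed=7, noise_sigma=0.0, class_label="benign")
    )
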