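import numpy as np
import pytest

from ontotraj import OntogenySpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_spec():
    """Zero-noise, zero-nuisance study-design spec."""
    return OntogenySpec(
        noise_sd=0.0,
        logcs_sd=0.0,
        rotation_nuisance=False,
        translation_range=0.0,
        n_per_cell=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_data(clean_spec):
    return generate_dataset(clean_spec)


@pytest.fixture(scope="session")
def noisy_data():
    """Study-condition dataset (defaults: noise, nuisance, 6 per cell)."""
    return generate_dataset(OntogenySpec(seed=7))


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q
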