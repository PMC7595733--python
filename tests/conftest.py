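import numpy as np
import pytest

import cardioem as ce


@pytest.fixture(scope="session")
def small_phantom() -> ce.EmPhantom:
    """Desk-scale EM phantom shared by read-only tests."""
    params = ce.EmPhantomParams(
        seed=101, grid_shape=(128, 128, 40), n_myofibrils=8,
        fibril_radius=40.0, fibril_length=600.0,
        theta_mean=45.0, theta_sd=20.0, phi_mean=30.0, phi_sd=15.0,
        n_nuclei=1, nucleus_semiaxes=(300.0, 200.0, 200.0),
        n_mitochondria=6, mito_semiaxes=(120.0, 90.0, 90.0),
        ec_fraction_target=0.2)
    return ce.generate_em_volume(params)


@pytest.fixture(scope="session")
def heart_phantom() -> ce.LabelVolume:
    return ce.generate_heart_phantom(ce.HeartPhantomParams(seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
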