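import numpy as np
import pytest

from dwifuse import default_scheme


@pytest.fixture(scope="session")
def scheme81():
    return default_scheme(81, seed=0)


@pytest.fixture(scope="session")
def scheme6():
    return default_scheme(6, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
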