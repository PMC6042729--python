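import numpy as np
import pytest

from dtihist.phantom import make_gradient_scheme
from dtihist.tensorfit import build_bmatrix


@pytest.fixture(scope="session")
def scheme15():
    """The study-shaped scheme: 1 b=0 + 15 directions at b=1000."""
    return make_gradient_scheme(15, 1000.0, seed=1)


@pytest.fixture(scope="session")
def bmatrix15(scheme15):
    return build_bmatrix(scheme15)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_psd_tensors(n, rng, scale=1e-3):
    """Random symmetric PSD tensors: rotated nonnegative eigenvalue triples.

    Returns (tensors6, eigenvalues_descending)."""
    evals = rng.uniform(0.0, 2.0 * scale, (n, 3))
    evals = -np.sort(-evals, axis=1)
    a = rng.standard_normal((n, 3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.einsum("vii->vi", r))[:, None, :]
    mats = np.einsum("vij,vj,vkj->vik", q, evals, q)
    t6 = np.stack([mats[:, 0, 0], mats[:, 1, 1], mats[:, 2, 2],
                   mats[:, 0, 1], mats[:, 0, 2], mats[:, 1, 2]], axis=-1)
    return t6, evals
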