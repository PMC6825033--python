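import numpy as np
import pytest

from fibrocrack.constitutive import FiberFrame, MaterialParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def material():
    return MaterialParams(mu=2.0, k1=1.5, k2=3.0, alpha=30.0, kappa=6.0)


@pytest.fixture
def frame():
    return FiberFrame.from_angle(30.0)


def random_deformation(rng, scale=0.25, n=None):
    """Random deformation gradients with guaranteed positive determinant."""
    shape = (3, 3) if n is None else (n, 3, 3)
    F = np.eye(3) + scale * rng.standard_normal(shape)
    det = np.linalg.det(F)
    while np.any(det < 0.2):
        bad = det < 0.2
        if n is None:
            F = np.eye(3) + scale * rng.standard_normal((3, 3))
        else:
            F[bad] = np.eye(3) + scale * rng.standard_normal((int(bad.sum()), 3, 3))
        det = np.linalg.det(F)
    return F
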