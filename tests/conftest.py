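import numpy as np
import pytest

from fearsense.geometry import BilinearTransform, Point2D
from fearsense.synthetic import default_face_features


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def face_features():
    return default_face_features()


@pytest.fixture
def generic_transform():
    """A mildly perspective-like bilinear transform used across tests."""
    return BilinearTransform(1.02, 0.015, 1e-5, 4.0, -0.01, 0.98, -8e-6, 2.5)


@pytest.fixture
def corner_points():
    return (
        Point2D(20.0, 25.0),
        Point2D(290.0, 30.0),
        Point2D(25.0, 210.0),
        Point2D(285.0, 205.0),
    )


def random_transform(rng) -> BilinearTransform:
    """A random, well-conditioned bilinear transform near a similarity."""
    coeffs = rng.normal(0.0, 0.05, 8)
    coeffs[0] += rng.uniform(0.8, 1.2)  # a near 1
    coeffs[5] += rng.uniform(0.8, 1.2)  # f near 1
    coeffs[2] = rng.normal(0.0, 1e-4)  # keep the xy terms small
    coeffs[6] = rng.normal(0.0, 1e-4)
    coeffs[3] = rng.normal(0.0, 20.0)  # translations
    coeffs[7] = rng.normal(0.0, 20.0)
    return BilinearTransform(*coeffs)
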