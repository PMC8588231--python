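import numpy as np
import pytest
from hypothesis import strategies as st

from edwfuse.grid import FusionGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_strict_geometry(rng, max_dim: int = 32, max_patch: int = 8) -> FusionGeometry:
    """Random small strict geometry: D = p + k*s per axis, volume <= max_dim^3."""
    shape, patch, stride = [], [], []
    for _ in range(3):
        p = int(rng.integers(1, max_patch + 1))
        s = int(rng.integers(1, p + 1))
        k_max = min((max_dim - p) // s, 4)
        k = int(rng.integers(0, k_max + 1))
        shape.append(p + k * s)
        patch.append(p)
        stride.append(s)
    return FusionGeometry(tuple(shape), tuple(patch), tuple(stride))


@st.composite
def small_geometries(draw, max_patch: int = 6, max_extra: int = 3):
    """Hypothesis strategy over valid strict geometries with tiny volumes."""
    shape, patch, stride = [], [], []
    for _ in range(3):
        p = draw(st.integers(1, max_patch))
        s = draw(st.integers(1, p))
        k = draw(st.integers(0, max_extra))
        shape.append(p + k * s)
        patch.append(p)
        stride.append(s)
    return FusionGeometry(tuple(shape), tuple(patch), tuple(stride))
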