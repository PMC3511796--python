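import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rehopipe.images import Bold4D, BrainMask

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def affine3mm():
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    aff[:3, 3] = (-30.0, -30.0, -30.0)
    return aff


@pytest.fixture
def make_bold(affine3mm):
    """Factory for small BOLD images from arbitrary 4D data."""

    def _make(data, tr_s=3.0):
        return Bold4D(data=np.asarray(data, dtype=float), affine=affine3mm, tr_s=tr_s)

    return _make


@pytest.fixture
def noise_bold(rng, make_bold):
    """White-noise 10x10x10x40 image at TR 3 s."""
    return make_bold(rng.standard_normal((10, 10, 10, 40)))


@pytest.fixture
def full_mask(affine3mm):
    def _make(shape):
        return BrainMask.full(shape, affine3mm)

    return _make
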