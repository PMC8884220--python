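import numpy as np
import pytest

from edofuse.simulate import PSFModel, SceneObject, SceneSpec
from edofuse.stack import ZStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack(rng):
    """A 5-plane random float stack, 64x64."""
    return ZStack(planes=rng.random((5, 64, 64, 3)), axial_step=0.5)


@pytest.fixture
def two_plane_halves(rng):
    """Two planes: left half sharp in plane 0, right half sharp in plane 1.

    Built from one random texture; the out-of-focus half of each plane is a
    heavily smoothed copy.
    """
    from scipy import ndimage

    base = rng.random((64, 64, 3))
    blurred = ndimage.gaussian_filter(base, (3.0, 3.0, 0))
    p0 = base.copy()
    p0[:, 32:] = blurred[:, 32:]
    p1 = base.copy()
    p1[:, :32] = blurred[:, :32]
    return ZStack(planes=np.stack([p0, p1]), axial_step=0.5), base


@pytest.fixture
def single_parasite_scene():
    """One parasite-like ring at a known depth in a small field."""
    obj = SceneObject(cls="parasite", center_xy=(48.0, 48.0), depth_z=1.2,
                      radius=18.0, color=(0.42, 0.28, 0.55), texture_seed=7)
    return SceneSpec(objects=[obj], field_size=96, sample_thickness=3.0)


@pytest.fixture
def psf():
    return PSFModel()
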