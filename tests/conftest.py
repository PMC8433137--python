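import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from splintnav.geometry import Frame, Transform
from splintnav.simulator import make_phantom


def random_rigid(rng: np.random.Generator, from_frame: Frame, to_frame: Frame,
                 trans_scale: float = 50.0) -> Transform:
    """A uniformly random rotation with a Gaussian translation."""
    r = Rotation.random(rng=rng).as_matrix()
    return Transform.from_rotation_translation(
        r, rng.normal(0.0, trans_scale, 3), from_frame, to_frame
    )


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
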