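import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def texture():
    """A 96x96 smooth broad-band texture for warping/similarity tests."""
    from evireg.fixtures import make_texture_image

    return make_texture_image("blobs", (96, 96), 42)


@pytest.fixture
def texture_pair():
    """Reference + sensed pair with a known mild rigid ground truth."""
    from evireg.fixtures import derive_pair, make_texture_image
    from evireg.geometry import RigidParams, image_center, rigid_to_matrix

    R = make_texture_image("blobs", (96, 96), 42)
    T = rigid_to_matrix(RigidParams(4.0, -3.0, 2.0), center=image_center(R.shape))
    S, _ = derive_pair(R, T, 0.0, 0)
    return R, S, T
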