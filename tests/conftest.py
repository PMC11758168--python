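import numpy as np
import pytest

from nerfrgbd.scene import CameraModel
from nerfrgbd import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def identity_camera(width=101, height=101, fx=100.0, fy=100.0, near=0.1, far=10.0,
                    translation=(0.0, 0.0, 0.0)):
    """Camera at the origin (or ``translation``) looking down world +z."""
    return CameraModel(
        camera_id="test",
        fx=fx, fy=fy, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
        width=width, height=height,
        rotation=np.eye(3), translation=np.asarray(translation, float),
        near=near, far=far,
    )


@pytest.fixture
def id_cam():
    return identity_camera()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small on-disk synthetic dataset for I/O and protocol tests."""
    out = tmp_path_factory.mktemp("tinyds")
    manifest = syn.make_dataset(
        syn.default_scene(), n_cameras=3, image_size=16, t_video=1,
        tof_cfg=syn.ToFArtifactConfig(border_margin=1), out_dir=out, seed=7,
    )
    return manifest
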