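import numpy as np
import pytest

from gerikit import synthetic


@pytest.fixture
def small_scene_config():
    """A desk-scale two-photon scene: 20 x 80 x 80 um at 1 x 0.5 x 0.5 um
    voxels, a dozen nuclei, noise off."""
    return synthetic.SceneConfig(
        volume_shape=(20, 160, 160),
        voxel_size=(1.0, 0.5, 0.5),
        n_nuclei=12,
        nucleus_radius_um=(4.0, 0.3),
        ts_fraction=0.5,
        autofluorescence_density=5,
        seed=1,
    )


@pytest.fixture
def smooth_volume():
    """A smooth random 3D intensity field (registration substrate)."""
    from scipy import ndimage
    rng = np.random.default_rng(0)
    return ndimage.gaussian_filter(rng.random((8, 64, 64)), 2) * 100.0
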