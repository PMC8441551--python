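import numpy as np
import pytest
from hypothesis import settings

import tdrm

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scene():
    """Small phantom with every truth class, reused across module tests."""
    spec = tdrm.PhantomSpec(
        grid_shape=(60, 60, 60),
        counts=dict(
            projection=50,
            commissural=60,
            short_assoc=80,
            long_assoc=70,
            noise_wm=30,
            ineffective=20,
        ),
        n_parcels_per_hemisphere=4,
        seed=7,
    )
    return tdrm.build_phantom(spec)


@pytest.fixture(scope="session")
def classified(scene):
    return tdrm.classify_tracks(scene.tracks, scene.tissue)


def make_line_tissue():
    """Tiny tissue volume where the voxel at (x, 0, 0) carries label x."""
    labels = np.zeros((5, 3, 3), dtype=np.int32)
    for x in range(5):
        labels[x, 0, 0] = x
    return tdrm.LabelVolume(labels=labels, affine=np.eye(4), role="tissue")


def track_between(label_a, label_b, n=5):
    """Straight streamline between the label voxels of make_line_tissue."""
    a = np.array([label_a, 0.0, 0.0])
    b = np.array([label_b, 0.0, 0.0])
    t = np.linspace(0, 1, n)[:, None]
    return a + t * (b - a)
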