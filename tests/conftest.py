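"""Shared fixtures: phantoms, scenes and study-condition constants.

Fixture conditions (chosen once, used everywhere): subtomogram work happens
in 32^3 boxes at 13.1 A/voxel, detection in 2x-binned tomograms at
21 A/voxel, the particle is 270 A across, and the subtomogram fixture SNR
(signal variance in the particle region / noise variance) is 1.0.
"""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tomopipe.core import DensityMap, RigidTransform, WedgeSpec
from tomopipe.simulate import PhantomSpec, build_phantom, make_subtomograms

SUB_VOXEL_A = 13.1
SUB_BOX = 32
DET_VOXEL_A = 21.0
PARTICLE_DIAMETER_A = 270.0
FIXTURE_SNR = 1.0


@pytest.fixture(scope="session")
def phantom_sub():
    """Phantom rendered at the subtomogram working scale."""
    return build_phantom(PhantomSpec(), SUB_VOXEL_A, SUB_BOX, seed=1)


@pytest.fixture(scope="session")
def phantom_det():
    """Phantom rendered at the detection (binned tomogram) scale."""
    return build_phantom(PhantomSpec(), DET_VOXEL_A, 20, seed=1)


@pytest.fixture(scope="session")
def base_map(phantom_sub):
    grid = phantom_sub.variants["base"].grid
    return DensityMap(grid - grid.mean(), SUB_VOXEL_A)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_pose(rng, max_shift_A=13.0):
    return RigidTransform(Rotation.random(rng=rng).as_matrix(),
                          rng.uniform(-max_shift_A, max_shift_A, 3))


def geodesic_deg(a, b):
    tr = float(np.trace(np.asarray(a).T @ np.asarray(b)))
    return math.degrees(math.acos(np.clip((tr - 1) / 2, -1.0, 1.0)))


def smooth_random_map(rng, n=32, sigma=2.0, voxel=SUB_VOXEL_A):
    from scipy.ndimage import gaussian_filter
    return DensityMap(gaussian_filter(rng.standard_normal((n,) * 3), sigma)
                      .astype(np.float32), voxel)
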