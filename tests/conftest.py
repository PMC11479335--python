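import numpy as np
import pytest

import vesseltrace as vt


def make_cylinder(radius: float = 4.0, length: int = 40, pad: int = 3,
                  spacing=(1.0, 1.0, 1.0)) -> vt.VoxelGrid:
    """Solid axis-aligned (x) cylinder with integer-center axis."""
    side = int(2 * (radius + pad) + 1)
    c = side // 2
    y, z = np.mgrid[0:side, 0:side]
    disk = (y - c) ** 2 + (z - c) ** 2 <= radius ** 2
    values = np.zeros((length + 2 * pad, side, side), dtype=np.uint8)
    values[pad:pad + length, disk] = 1
    return vt.VoxelGrid(values, spacing)


def cylinder_axis_center(radius: float = 4.0, pad: int = 3) -> int:
    return int(2 * (radius + pad) + 1) // 2


def make_ball(radius: int = 5, pad: int = 4) -> vt.VoxelGrid:
    side = 2 * (radius + pad) + 1
    c = radius + pad
    x, y, z = np.mgrid[0:side, 0:side, 0:side]
    values = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius ** 2).astype(np.uint8)
    return vt.VoxelGrid(values)


def make_y_skeleton():
    """One-voxel Y: trunk along x, two arms diverging in y. Returns
    (SkeletonMask, seed, arm_a_voxels, arm_b_voxels, tip_a, tip_b)."""
    values = np.zeros((21, 21, 5), dtype=np.uint8)
    trunk = [(i, 10, 2) for i in range(0, 10)]
    arm_a = [(10 + i, 10 + i, 2) for i in range(1, 9)]
    arm_b = [(10 + i, 10 - i, 2) for i in range(1, 9)]
    for v in trunk + [(10, 10, 2)] + arm_a + arm_b:
        values[v] = 1
    skel = vt.SkeletonMask(values)
    return skel, trunk[0], arm_a, arm_b, arm_a[-1], arm_b[-1]


def brute_force_edt(values: np.ndarray, sampling=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Literal minimization over all background voxels (the defining form)."""
    from scipy.spatial.distance import cdist

    values = np.asarray(values)
    sp = np.asarray(sampling, dtype=float)
    fg = np.argwhere(values != 0)
    bg = np.argwhere(values == 0)
    if len(bg) == 0:
        raise ValueError("no background voxel")
    out = np.zeros(values.shape, dtype=float)
    if len(fg):
        out[tuple(fg.T)] = cdist(fg * sp, bg * sp).min(axis=1)
    return out


@pytest.fixture(scope="session")
def cylinder_grid():
    return make_cylinder()


@pytest.fixture(scope="session")
def ball_grid():
    return make_ball()


@pytest.fixture(scope="session")
def y_skeleton():
    return make_y_skeleton()


@pytest.fixture(scope="session")
def phantom_straight():
    """Zero-bifurcation straight tube, tortuosity 0."""
    tree = vt.generate_spline_tree(n_bifurcations=0, tortuosity=0.0, seed=3)
    return vt.rasterize_tree(tree)


@pytest.fixture(scope="session")
def phantom_bif3():
    """Three-bifurcation phantom (four terminal branches)."""
    tree = vt.generate_spline_tree(n_bifurcations=3, seed=2)
    return vt.rasterize_tree(tree)


@pytest.fixture(scope="session")
def extraction_bif3(phantom_bif3):
    ph = phantom_bif3
    return vt.extract_tree(ph.grid, ph.seed_voxel(), ph.leaf_goal_voxels())
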