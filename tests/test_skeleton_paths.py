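import numpy as np
import pytest

import vesseltrace as vt
from vesseltrace.skeleton_paths import nearest_skeleton_voxel, neighbor_offsets
from conftest import cylinder_axis_center, make_cylinder


def simple_bfs_depths(values, seed, connectivity):
    """Independent shortest-path oracle: plain dict-based BFS."""
    from collections import deque

    offs = neighbor_offsets(connectivity)
    depth = {seed: 0}
    q = deque([seed])
    while q:
        cur = q.popleft()
        for off in offs:
            nb = tuple(cur[a] + off[a] for a in range(3))
            if (all(0 <= nb[a] < values.shape[a] for a in range(3))
                    and values[nb] and nb not in depth):
                depth[nb] = depth[cur] + 1
                q.append(nb)
    return depth


class TestSkeletonize:
    def test_thin_line_is_fixed_point(self):
        values = np.zeros((20, 5, 5), dtype=np.uint8)
        values[2:18, 2, 2] = 1
        skel = vt.extract_skeleton(vt.VoxelGrid(values))
        np.testing.assert_array_equal(skel.values, values)

    def test_empty_foreground(self):
        skel = vt.extract_skeleton(vt.VoxelGrid(np.zeros((4, 4, 4))))
        assert skel.values.sum() == 0

    def test_single_voxel_retained(self):
        values = np.zeros((5, 5, 5), dtype=np.uint8)
        values[2, 2, 2] = 1
        assert vt.extract_skeleton(vt.VoxelGrid(values)).values.sum() == 1

    def test_cylinder_skeleton_thin_and_central(self):
        grid = make_cylinder(radius=4.0, length=40)
        c = cylinder_axis_center(4.0)
        skel = vt.extract_skeleton(grid)
        assert skel.values.sum() < 0.15 * grid.foreground_count()
        vox = skel.voxels()
        lateral = np.sqrt((vox[:, 1] - c) ** 2 + (vox[:, 2] - c) ** 2)
        assert lateral.max() <= 2.0
        assert np.all(grid.values[tuple(vox.T)] == 1)  # subset of foreground


class TestBfsDepthMap:
    def test_worked_5x5_example(self):
        """4-adjacent BFS on a 5x5 all-foreground slice: corner-to-corner depth 8."""
        skel = vt.SkeletonMask(np.ones((5, 5, 1), dtype=np.uint8))
        dm = vt.bfs_depth_map(skel, (0, 0, 0), connectivity="faces")
        assert dm.depth_at((0, 0, 0)) == 0
        assert dm.depth_at((4, 4, 0)) == 8
        # every depth equals the Manhattan distance from the corner seed
        x, y = np.mgrid[0:5, 0:5]
        np.testing.assert_array_equal(dm.values[:, :, 0], x + y)

    def test_background_is_minus_one(self):
        values = np.ones((5, 5, 1), dtype=np.uint8)
        values[2, 2, 0] = 0
        dm = vt.bfs_depth_map(vt.SkeletonMask(values), (0, 0, 0), "faces")
        assert dm.values[2, 2, 0] == -1

    def test_seed_off_skeleton_names_nearest(self):
        values = np.zeros((5, 5, 5), dtype=np.uint8)
        values[1, 1, 1] = 1
        with pytest.raises(ValueError, match=r"\(1, 1, 1\)"):
            vt.bfs_depth_map(vt.SkeletonMask(values), (4, 4, 4))

    @pytest.mark.parametrize("connectivity", ["faces", "faces+edges+corners"])
    def test_matches_independent_bfs(self, y_skeleton, connectivity):
        skel, seed, *_ = y_skeleton
        dm = vt.bfs_depth_map(skel, seed, connectivity)
        oracle = simple_bfs_depths(skel.values, seed, connectivity)
        for v in map(tuple, skel.voxels()):
            assert dm.depth_at(v) == oracle.get(v, -1)
        assert np.all(dm.values[skel.values == 0] == -1)

    def test_rerun_reproduces_map_bitwise(self, y_skeleton):
        skel, seed, *_ = y_skeleton
        a = vt.bfs_depth_map(skel, seed)
        b = vt.bfs_depth_map(skel, seed)
        np.testing.assert_array_equal(a.values, b.values)


class TestBestPath:
    def test_worked_5x5_path(self):
        skel = vt.SkeletonMask(np.ones((5, 5, 1), dtype=np.uint8))
        dm = vt.bfs_depth_map(skel, (0, 0, 0), connectivity="faces")
        bp = vt.best_path(dm, (4, 4, 0))
        assert len(bp) == 9
        np.testing.assert_array_equal(bp.depths, np.arange(9))
        assert tuple(bp.points[0]) == (0, 0, 0)
        assert tuple(bp.points[-1]) == (4, 4, 0)

    def test_goal_equals_seed(self):
        skel = vt.SkeletonMask(np.ones((3, 3, 1), dtype=np.uint8))
        dm = vt.bfs_depth_map(skel, (1, 1, 0), connectivity="faces")
        bp = vt.best_path(dm, (1, 1, 0))
        assert len(bp) == 1

    def test_unreached_goal_rejected(self):
        values = np.zeros((5, 5, 1), dtype=np.uint8)
        values[0, 0, 0] = 1
        values[4, 4, 0] = 1
        dm = vt.bfs_depth_map(vt.SkeletonMask(values), (0, 0, 0), "faces")
        with pytest.raises(ValueError, match="unreached"):
            vt.best_path(dm, (4, 4, 0))

    def test_length_is_depth_plus_one(self, y_skeleton):
        skel, seed, _, _, tip_a, tip_b = y_skeleton
        dm = vt.bfs_depth_map(skel, seed)
        for goal in (tip_a, tip_b):
            bp = vt.best_path(dm, goal)
            assert len(bp) == dm.depth_at(goal) + 1
            steps = np.abs(np.diff(bp.points, axis=0)).max(axis=1)
            assert np.all(steps == 1)  # valid 26-connected chain

    def test_false_branch_excluded(self, y_skeleton):
        """With the goal on arm A, no voxel of arm B appears on the path."""
        skel, seed, arm_a, arm_b, tip_a, _ = y_skeleton
        dm = vt.bfs_depth_map(skel, seed)
        bp = vt.best_path(dm, tip_a)
        path_voxels = set(map(tuple, bp.points))
        assert path_voxels.isdisjoint(set(arm_b))
        assert tuple(bp.points[-1]) == tip_a

    def test_random_skeletons_shortest_path(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            values = (rng.random((7, 7, 3)) < 0.6).astype(np.uint8)
            values[0, 0, 0] = 1
            skel = vt.SkeletonMask(values)
            dm = vt.bfs_depth_map(skel, (0, 0, 0))
            oracle = simple_bfs_depths(values, (0, 0, 0), "faces+edges+corners")
            reached = [v for v, d in oracle.items() if d > 0]
            if not reached:
                continue
            goal = max(reached, key=lambda v: oracle[v])
            bp = vt.best_path(dm, goal)
            assert len(bp) - 1 == oracle[goal]


def test_nearest_skeleton_voxel():
    values = np.zeros((5, 5, 5), dtype=np.uint8)
    values[1, 1, 1] = values[3, 3, 3] = 1
    near, dist = nearest_skeleton_voxel(vt.SkeletonMask(values), (0, 0, 0))
    assert near == (1, 1, 1)
    assert dist == pytest.approx(np.sqrt(3))
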