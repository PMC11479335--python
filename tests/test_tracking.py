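import numpy as np
import pytest

import vesseltrace as vt
from vesseltrace.centerpoints import Centerpoint
from vesseltrace.skeleton_paths import BestPath
from vesseltrace.tracking import (CandidateExhaustedError, CenterPath,
                                  CenterlineMap, densify_path)
from conftest import cylinder_axis_center, make_cylinder


class TestCubeBounds:
    def test_interior(self):
        b = vt.cube_bounds((10, 10, 10), 3, (64, 64, 64))
        assert b.as_tuple() == (7, 13, 7, 13, 7, 13)

    def test_lower_clamp(self):
        b = vt.cube_bounds((1, 1, 1), 3, (64, 64, 64))
        assert (b.x1, b.y1, b.z1) == (0, 0, 0)
        assert (b.x2, b.y2, b.z2) == (4, 4, 4)

    def test_upper_clamp(self):
        b = vt.cube_bounds((62, 62, 62), 3, (64, 64, 64))
        assert (b.x2, b.y2, b.z2) == (63, 63, 63)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            vt.cube_bounds((70, 0, 0), 2, (64, 64, 64))


class TestNextCandidate:
    def test_unique_positive_voxel(self):
        vals = np.zeros((9, 9, 9))
        vals[2, 4, 4] = 3.0  # on the x-low face of the cube below
        b = vt.cube_bounds((4, 4, 4), 2, vals.shape)
        cand = vt.next_candidate(vals, b)
        assert cand.index == (2, 4, 4)
        assert cand.radius == 3.0

    def test_all_zero_faces_exhausted(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 5.0  # interior only; faces are all zero
        b = vt.cube_bounds((4, 4, 4), 2, vals.shape)
        with pytest.raises(CandidateExhaustedError):
            vt.next_candidate(vals, b)

    def test_excluded_voxels_skipped(self):
        vals = np.zeros((9, 9, 9))
        vals[2, 4, 4] = 3.0
        vals[6, 4, 4] = 2.0
        b = vt.cube_bounds((4, 4, 4), 2, vals.shape)
        cand = vt.next_candidate(vals, b, excluded=[(2, 4, 4)])
        assert cand.index == (6, 4, 4)

    def test_cylinder_candidate_on_axis_face(self):
        """Inside a straight tube the face maximum sits on-axis, one radius
        ahead or behind along the tube."""
        grid = make_cylinder(radius=4.0, length=40)
        c = cylinder_axis_center(4.0)
        d = vt.euclidean_distance_map(grid, units="voxel")
        center = (20, c, c)
        b = vt.cube_bounds(center, 4, grid.shape)
        cand = vt.next_candidate(d.values, b)
        assert cand.index[0] in (16, 24)
        assert abs(cand.index[1] - c) <= 1 and abs(cand.index[2] - c) <= 1
        # brute-force maximum over all six faces agrees
        face_vals = []
        for x in range(16, 25):
            for y in range(c - 4, c + 5):
                for z in range(c - 4, c + 5):
                    if x in (16, 24) or y in (c - 4, c + 4) or z in (c - 4, c + 4):
                        face_vals.append(d.values[x, y, z])
        assert cand.radius == max(face_vals)


class TestSphereIntersection:
    def _path(self):
        pts = [(i, 0, 0) for i in range(10)]
        return BestPath(points=pts, depths=list(range(10)))

    def test_centered_on_path_voxel(self):
        assert vt.sphere_intersects_path(Centerpoint((5, 0, 0), 1.0), self._path())

    def test_separated(self):
        assert not vt.sphere_intersects_path(Centerpoint((5, 9, 0), 2.0), self._path())

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        path = self._path()
        for _ in range(50):
            c = tuple(int(v) for v in rng.integers(0, 12, 3))
            r = float(rng.uniform(0.5, 4.0))
            expected = any(np.linalg.norm(np.subtract(c, p)) <= r for p in path.points)
            assert vt.sphere_intersects_path(Centerpoint(c, r), path) == expected

    def test_spacing_weighted(self):
        path = self._path()
        cand = Centerpoint((5, 2, 0), 1.5)
        assert not vt.sphere_intersects_path(cand, path, spacing=(1, 1, 1))
        assert vt.sphere_intersects_path(cand, path, spacing=(1, 0.5, 1))


@pytest.fixture(scope="module")
def tracked_cylinder():
    """Straight tube with on-axis seed/goal centerpoints, away from the caps."""
    grid = make_cylinder(radius=4.0, length=60)
    c = cylinder_axis_center(4.0)
    dmap = vt.euclidean_distance_map(grid)
    skel = vt.extract_skeleton(grid)
    from vesseltrace.skeleton_paths import nearest_skeleton_voxel

    seed = Centerpoint((8, c, c), float(dmap.values[8, c, c]))
    goal = Centerpoint((57, c, c), float(dmap.values[57, c, c]))
    sseed, _ = nearest_skeleton_voxel(skel, seed.index)
    sgoal, _ = nearest_skeleton_voxel(skel, goal.index)
    dm = vt.bfs_depth_map(skel, sseed)
    bp = vt.best_path(dm, sgoal)
    path = vt.track_centerline(dmap, bp, seed, goal)
    return grid, c, seed, goal, path


class TestTrackCenterline:

    def test_points_near_axis(self, tracked_cylinder):
        _, c, _, _, path = tracked_cylinder
        lateral = np.sqrt((path.points[:, 1] - c) ** 2.0 + (path.points[:, 2] - c) ** 2.0)
        assert lateral.max() <= 1.0 + 1e-9

    def test_monotone_progress_and_termination(self, tracked_cylinder):
        _, _, seed, goal, path = tracked_cylinder
        assert tuple(path.points[0]) == seed.index
        assert tuple(path.points[-1]) == goal.index
        x = path.points[:, 0]
        assert np.all(np.diff(x[:-1]) > 0)  # advances along the tube each step

    def test_all_points_foreground_positive_radii(self, tracked_cylinder):
        grid, _, _, _, path = tracked_cylinder
        assert np.all(grid.values[tuple(path.points.T)] == 1)
        assert np.all(path.radii > 0)

    def test_goal_inside_first_sphere(self):
        grid = make_cylinder(radius=4.0, length=12)
        c = cylinder_axis_center(4.0)
        dmap = vt.euclidean_distance_map(grid)
        seed = Centerpoint((6, c, c), float(dmap.values[6, c, c]))
        goal = Centerpoint((8, c, c), float(dmap.values[8, c, c]))
        bp = BestPath(points=[(i, c, c) for i in range(6, 9)], depths=[0, 1, 2])
        path = vt.track_centerline(dmap, bp, seed, goal)
        assert len(path) == 2
        assert tuple(path.points[-1]) == goal.index

    def test_wrong_branch_avoided(self, phantom_bif3, extraction_bif3):
        """No tracked point lies deeper than one candidate radius into a
        branch off its own root-to-leaf chain (arc-depth oracle from the
        phantom's ground truth)."""
        ph = phantom_bif3
        sp = np.asarray(ph.grid.spacing)
        leaves = ph.tree.leaves()
        # per-branch cumulative arc length of the truth polylines
        arc = []
        for tr in ph.truth_points:
            seg = np.linalg.norm(np.diff(tr, axis=0), axis=1)
            arc.append(np.concatenate(([0.0], np.cumsum(seg))))
        for g, leaf in zip(extraction_bif3.goals, leaves):
            own_chain = set(ph.tree.root_to_leaf(leaf))
            for p, r in zip(g["center_path"].points.astype(float) * sp,
                            g["center_path"].radii):
                # nearest truth point over all branches
                best = min(range(len(ph.truth_points)), key=lambda b: float(
                    np.min(np.linalg.norm(ph.truth_points[b] - p, axis=1))))
                if best in own_chain:
                    continue
                i = int(np.argmin(np.linalg.norm(ph.truth_points[best] - p, axis=1)))
                depth_into = float(arc[best][i])  # arc distance from branch origin
                assert depth_into <= r + float(np.linalg.norm(sp)), (
                    f"point {p} is {depth_into:.1f} mm into branch {best}")


class TestMergeIntoTree:
    def _path(self, pts):
        return CenterPath(points=pts, radii=np.ones(len(pts)))

    def test_first_path_sets_chain(self):
        cmap = CenterlineMap.zeros((10, 10, 3))
        path = self._path([(1, 1, 1), (4, 1, 1), (8, 1, 1)])
        cmap, info = vt.merge_into_tree(path, cmap)
        assert info["junction"] is None
        assert cmap.values.sum() == len(info["added"]) == len(densify_path(path.points))
        # every tracked point is present in the map
        assert np.all(cmap.values[tuple(path.points.T)] == 1)

    def test_shared_trunk_counted_once(self):
        """A second path sharing a trunk only adds its divergent arm."""
        cmap = CenterlineMap.zeros((12, 12, 3))
        trunk = [(i, 5, 1) for i in range(0, 6)]
        a = self._path(trunk + [(6, 6, 1), (7, 7, 1)])
        b = self._path(trunk + [(6, 4, 1), (7, 3, 1)])
        cmap, info_a = vt.merge_into_tree(a, cmap)
        n_a = int(cmap.values.sum())
        cmap, info_b = vt.merge_into_tree(b, cmap)
        assert info_b["junction"] == (5, 5, 1)  # end of the shared trunk
        # no trunk voxel written twice: added voxels are all new and off-trunk
        assert set(info_b["added"]).isdisjoint(set(info_a["added"]))
        assert int(cmap.values.sum()) == n_a + len(info_b["added"])
        assert set(info_b["added"]) == {(7, 3, 1), (6, 4, 1)}

    def test_idempotent(self):
        cmap = CenterlineMap.zeros((10, 10, 3))
        path = self._path([(1, 1, 1), (5, 5, 1)])
        cmap, _ = vt.merge_into_tree(path, cmap)
        before = cmap.values.copy()
        cmap, info = vt.merge_into_tree(path, cmap)
        np.testing.assert_array_equal(cmap.values, before)
        assert info["added"] == []

    def test_outside_voxel_rejected(self):
        cmap = CenterlineMap.zeros((4, 4, 4))
        with pytest.raises(ValueError, match="outside"):
            vt.merge_into_tree(self._path([(1, 1, 1), (9, 1, 1)]), cmap)
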