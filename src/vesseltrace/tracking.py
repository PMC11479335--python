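"""Smooth centerline tracking on the distance map, guided by the best path.

Starting at the seed, a cube of radius r (the distance-map value at the
current point, in voxels) is built around the current point. The six
faces of the cube are scanned for the voxel with the largest distance
value — on a tube that voxel sits on the medial axis one radius ahead or
behind. Each candidate is validated against the best path: a sphere of
the candidate's own radius is placed at the candidate and must overlap
the best path *ahead* of the point already reached. A candidate whose
sphere misses the path (or only touches ground already covered) is the
entrance of a wrong branch at a bifurcation; it is zeroed on a private
working copy of the map and the next-highest face voxel is tried, from
the previous accepted point, until an acceptable direction is found.
Tracking stops when the goal falls inside the current sphere.

Per-goal centerlines are merged into a one-voxel-thick tree by growing
each new path from its goal end toward the seed and halting at the first
voxel already occupied by an earlier centerline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .centerpoints import Centerpoint
from .distance_map import DistanceMap
from .skeleton_paths import BestPath

__all__ = [
    "CubeBounds",
    "CenterPath",
    "CenterlineMap",
    "CandidateExhaustedError",
    "TrackingFailedError",
    "cube_bounds",
    "next_candidate",
    "sphere_intersects_path",
    "track_centerline",
    "merge_into_tree",
    "densify_path",
]


class CandidateExhaustedError(RuntimeError):
    """All six cube faces hold no positive, non-excluded distance value."""


class TrackingFailedError(RuntimeError):
    """Tracking could not reach the goal; carries the last accepted point."""

    def __init__(self, message: str, last_point=None):
        super().__init__(message)
        self.last_point = last_point


@dataclass(frozen=True)
class CubeBounds:
    """Inclusive per-axis voxel bounds of a search cube."""

    x1: int
    x2: int
    y1: int
    y2: int
    z1: int
    z2: int

    def __post_init__(self):
        for a1, a2 in ((self.x1, self.x2), (self.y1, self.y2), (self.z1, self.z2)):
            if not 0 <= a1 <= a2:
                raise ValueError(f"invalid cube bounds {self}")

    def as_tuple(self):
        return (self.x1, self.x2, self.y1, self.y2, self.z1, self.z2)


@dataclass
class CenterPath:
    """Tracked centerline: ordered voxels, seed first, with per-point radii (mm)."""

    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        if len(self.points) != len(self.radii):
            raise ValueError("points and radii lengths differ")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CenterlineMap:
    """Binary accumulation volume for merged centerlines."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(np.uint8)

    @classmethod
    def zeros(cls, shape) -> "CenterlineMap":
        return cls(np.zeros(shape, dtype=np.uint8))


def cube_bounds(center, r: int, shape) -> CubeBounds:
    """Axis-aligned cube [a-r, a+r] per axis, clamped to the grid.

    ``r`` is in voxels and must be >= 1 after the caller's discretization.
    """
    center = tuple(int(v) for v in center)
    if not all(0 <= center[a] < shape[a] for a in range(3)):
        raise ValueError(f"cube center {center} outside grid of shape {tuple(shape)}")
    r = int(r)
    if r < 1:
        raise ValueError(f"cube radius must be >= 1 voxel, got {r}")
    lo = [max(0, center[a] - r) for a in range(3)]
    hi = [min(shape[a] - 1, center[a] + r) for a in range(3)]
    return CubeBounds(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


def _face_slices(b: CubeBounds):
    """The six cube faces in fixed scan order: x-low, x-high, y-low, y-high, z-low, z-high."""
    return [
        (slice(b.x1, b.x1 + 1), slice(b.y1, b.y2 + 1), slice(b.z1, b.z2 + 1)),
        (slice(b.x2, b.x2 + 1), slice(b.y1, b.y2 + 1), slice(b.z1, b.z2 + 1)),
        (slice(b.x1, b.x2 + 1), slice(b.y1, b.y1 + 1), slice(b.z1, b.z2 + 1)),
        (slice(b.x1, b.x2 + 1), slice(b.y2, b.y2 + 1), slice(b.z1, b.z2 + 1)),
        (slice(b.x1, b.x2 + 1), slice(b.y1, b.y2 + 1), slice(b.z1, b.z1 + 1)),
        (slice(b.x1, b.x2 + 1), slice(b.y1, b.y2 + 1), slice(b.z2, b.z2 + 1)),
    ]


def next_candidate(dmap_values: np.ndarray, bounds: CubeBounds, excluded=()) -> Centerpoint:
    """Voxel with the maximum distance value over the six cube faces.

    Excluded voxels and non-positive values are skipped. The global
    maximum wins; ties go to the earlier face in the fixed scan order and
    then to the lexicographically smallest coordinate within the face.
    """
    excluded = set(tuple(int(v) for v in p) for p in excluded)
    best_val = 0.0
    best_pt = None
    for sl in _face_slices(bounds):
        face = dmap_values[sl]
        if excluded:
            face = face.copy()
            off = (sl[0].start, sl[1].start, sl[2].start)
            for p in excluded:
                li = (p[0] - off[0], p[1] - off[1], p[2] - off[2])
                if all(0 <= li[a] < face.shape[a] for a in range(3)):
                    face[li] = 0.0
        flat = int(np.argmax(face))  # first occurrence = lexicographic min in face
        val = float(face.flat[flat])
        if val > best_val:
            li = np.unravel_index(flat, face.shape)
            best_val = val
            best_pt = (sl[0].start + int(li[0]), sl[1].start + int(li[1]),
                       sl[2].start + int(li[2]))
    if best_pt is None:
        raise CandidateExhaustedError(
            f"no positive distance value on the faces of cube {bounds.as_tuple()}"
        )
    return Centerpoint(index=best_pt, radius=best_val)


def sphere_intersects_path(candidate: Centerpoint, path: BestPath,
                           spacing=(1.0, 1.0, 1.0)) -> bool:
    """True iff any best-path voxel lies within the candidate's closed ball.

    The ball radius is the candidate's distance value; distances are
    measured in physical units using ``spacing``.
    """
    if candidate.radius <= 0:
        raise ValueError("candidate radius must be positive")
    if len(path) == 0:
        raise ValueError("best path is empty")
    sp = np.asarray(spacing, dtype=float)
    pts = path.points.astype(float) * sp
    c = np.asarray(candidate.index, dtype=float) * sp
    d2 = ((pts - c) ** 2).sum(axis=1)
    return bool(np.any(d2 <= candidate.radius ** 2))


def _path_progress(tree: cKDTree, center, radius: float, sp: np.ndarray) -> int:
    """Largest best-path index inside the ball at ``center``; -1 if none."""
    c = np.asarray(center, dtype=float) * sp
    hits = tree.query_ball_point(c, r=float(radius))
    return max(hits) if hits else -1


def track_centerline(dmap: DistanceMap, path: BestPath, seed: Centerpoint,
                     goal: Centerpoint, max_iter: int | None = None) -> CenterPath:
    """Walk seed -> goal on the distance map via cube-face maxima.

    The best path acts as directional reference: a candidate is accepted
    only if its sphere reaches a best-path voxel strictly beyond the
    furthest path voxel already covered, which both rejects wrong-branch
    candidates at bifurcations and forbids retrograde motion. Rejected
    candidates are zeroed on a private working copy (the pristine map is
    used for the reported radii and stays valid for later goals); when a
    cube is exhausted the walk backtracks to the previous accepted point.
    Terminates when the goal lies within the current sphere or within one
    voxel of the current point, appending the goal as the final point.
    """
    sp = np.asarray(dmap.spacing if dmap.units == "mm" else (1.0, 1.0, 1.0), dtype=float)
    min_sp = float(sp.min())
    shape = dmap.shape
    work = dmap.values.copy()
    path_phys = path.points.astype(float) * sp
    tree = cKDTree(path_phys)

    seed_idx = tuple(int(v) for v in seed.index)
    goal_idx = tuple(int(v) for v in goal.index)
    goal_phys = np.asarray(goal_idx, dtype=float) * sp

    accepted = [seed_idx]
    visited = {seed_idx}
    progress = _path_progress(tree, seed_idx, dmap.values[seed_idx], sp)
    if max_iter is None:
        fg = int(np.count_nonzero(dmap.values))
        max_iter = int(50 * max(1.0, fg) ** (1 / 3)) + 1000

    iters = 0
    while True:
        cur = accepted[-1]
        cur_r = float(dmap.values[cur])
        # goal detection: inside the current sphere, voxel-adjacent, or the
        # sphere has swept past the final best-path voxel (the goal's
        # skeleton snap), beyond which the reference path carries no
        # further direction
        goal_d = float(np.linalg.norm((np.asarray(cur, float) * sp) - goal_phys))
        if (goal_d <= cur_r
                or max(abs(cur[a] - goal_idx[a]) for a in range(3)) <= 1
                or progress >= len(path) - 1):
            if cur != goal_idx:
                accepted.append(goal_idx)
            break
        r_vox = max(1, int(round(cur_r / min_sp)))
        bounds = cube_bounds(cur, r_vox, shape)
        while True:
            iters += 1
            if iters > max_iter:
                raise TrackingFailedError(
                    f"iteration cap {max_iter} exceeded; last accepted point {cur}",
                    last_point=cur,
                )
            try:
                cand = next_candidate(work, bounds, excluded=visited)
            except CandidateExhaustedError:
                if len(accepted) > 1:
                    accepted.pop()  # dead end: return to the previous centerpoint
                    break
                raise TrackingFailedError(
                    f"no acceptable direction from the seed {seed_idx}",
                    last_point=seed_idx,
                ) from None
            cand_progress = _path_progress(tree, cand.index, cand.radius, sp)
            if cand_progress > progress:
                accepted.append(cand.index)
                visited.add(cand.index)
                progress = cand_progress
                break
            # wrong branch or retrograde: discard and retry from the same point
            work[cand.index] = 0.0

    pts = np.asarray(accepted, dtype=np.int64)
    radii = dmap.values[pts[:, 0], pts[:, 1], pts[:, 2]].astype(float)
    # the snapped goal always carries a positive map value, but guard radii anyway
    radii = np.maximum(radii, min_sp)
    return CenterPath(points=pts, radii=radii)


def densify_path(points: np.ndarray) -> np.ndarray:
    """Connect consecutive path points with 26-connected voxel segments.

    Tracked points are about one radius apart; rasterizing each segment
    (uniform sampling at half-voxel steps, rounded) yields a connected
    one-voxel chain suitable for the centerline map.
    """
    points = np.asarray(points, dtype=np.int64)
    if len(points) == 0:
        return points
    out = [tuple(points[0])]
    for a, b in zip(points[:-1], points[1:]):
        n = int(np.max(np.abs(b - a))) * 2
        for t in np.linspace(0.0, 1.0, max(n, 1) + 1)[1:]:
            v = tuple(int(round(c)) for c in (a + t * (b - a)))
            if v != out[-1]:
                out.append(v)
    return np.asarray(out, dtype=np.int64)


def _shortcut_chain(seq: list) -> list:
    """Greedy simplification of an adjacent voxel chain.

    From each voxel, jump directly to the farthest later chain voxel
    that is still 26-adjacent, dropping everything in between. This
    removes one-voxel zigzags and short doubled-back runs (which would
    thicken the centerline map to 2x2 locally) while preserving both
    endpoints, connectivity, and membership in the original chain.
    """
    if len(seq) <= 2:
        return list(seq)
    out = [seq[0]]
    i = 0
    while i < len(seq) - 1:
        j = len(seq) - 1
        while j > i + 1 and max(abs(seq[j][a] - seq[i][a]) for a in range(3)) > 1:
            j -= 1
        out.append(seq[j])
        i = j
    return out


def merge_into_tree(path: CenterPath, cmap: CenterlineMap) -> tuple[CenterlineMap, dict]:
    """Grow a tracked path into the centerline map from its goal end.

    The path is densified to a voxel chain and walked goal-to-seed; the
    walk halts at the first voxel already set to 1 (the junction with an
    existing centerline), so shared trunks are written once. Before
    writing, the chain is simplified by the farthest-adjacent shortcut,
    which keeps the map one voxel thick where the raw chain zigzags or
    slides in next to an existing line at the junction. Returns the map
    and a merge record with the voxels added and the junction voxel
    (None for the first path).
    """
    chain = densify_path(path.points)
    if np.any(chain < 0) or np.any(chain >= np.asarray(cmap.values.shape)):
        raise ValueError("path voxel outside the centerline map")
    walk = []
    junction = None
    for v in map(tuple, chain[::-1]):  # goal end first
        if cmap.values[v]:
            junction = v
            break
        walk.append(v)
    seq = _shortcut_chain(walk + ([junction] if junction is not None else []))
    added = [v for v in seq if v != junction]
    for v in added:
        cmap.values[v] = 1
    return cmap, {"added": added, "junction": junction}
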