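"""Skeleton extraction, BFS depth maps, and false-branch-free best paths.

The medial-axis skeleton of the binary mask is a cheap but noisy
centerline estimate: thinning of real vessel masks produces spurious
side branches. Running a breadth-first search over the skeleton from the
seed assigns every skeleton voxel its BFS depth (shortest step count
from the seed); walking from a goal voxel strictly downhill in depth,
one step at a time, recovers the unique-length shortest path back to
the seed and never enters a false branch, because voxels on a dead-end
branch can only be reached through its root.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import product

import numpy as np
from skimage.morphology import skeletonize

from .volume_io import VoxelGrid

__all__ = [
    "SkeletonMask",
    "DepthMap",
    "BestPath",
    "extract_skeleton",
    "bfs_depth_map",
    "best_path",
    "neighbor_offsets",
    "nearest_skeleton_voxel",
]

_CONNECTIVITIES = ("faces", "faces+edges+corners")


def neighbor_offsets(connectivity: str) -> list[tuple[int, int, int]]:
    """Neighbor offsets in lexicographic order for a connectivity tag.

    "faces" is 6-adjacency (4 in a one-slice grid); "faces+edges+corners"
    is full 26-adjacency. The fixed lexicographic order makes every BFS
    and backtrack in this module deterministic.
    """
    if connectivity == "faces":
        offs = [(-1, 0, 0), (0, -1, 0), (0, 0, -1), (0, 0, 1), (0, 1, 0), (1, 0, 0)]
    elif connectivity == "faces+edges+corners":
        offs = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    else:
        raise ValueError(f"connectivity must be one of {_CONNECTIVITIES}, got {connectivity!r}")
    return sorted(offs)


@dataclass
class SkeletonMask:
    """One-voxel-thick skeleton; subset of the source foreground."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(np.uint8)

    @property
    def shape(self):
        return self.values.shape

    def voxels(self) -> np.ndarray:
        return np.argwhere(self.values)


@dataclass
class DepthMap:
    """Integer BFS depth per voxel; -1 marks background/unreached."""

    values: np.ndarray
    seed: tuple[int, int, int]
    connectivity: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)
        self.seed = tuple(int(v) for v in self.seed)

    def depth_at(self, point) -> int:
        return int(self.values[tuple(int(v) for v in point)])


@dataclass
class BestPath:
    """Seed-to-goal skeleton path; depths increase by exactly 1 per step."""

    points: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int32)

    def __len__(self) -> int:
        return len(self.points)


def extract_skeleton(grid: VoxelGrid) -> SkeletonMask:
    """Topology-preserving 3D thinning of the mask (Lee-style).

    Returns an empty skeleton for an empty foreground. The result is a
    subset of the foreground and one voxel thick.
    """
    if grid.foreground_count() == 0:
        return SkeletonMask(np.zeros(grid.shape, dtype=np.uint8))
    skel = skeletonize(grid.values.astype(bool))
    return SkeletonMask(skel.astype(np.uint8))


def nearest_skeleton_voxel(skel: SkeletonMask, point) -> tuple[tuple[int, int, int], float]:
    """Nearest skeleton voxel to ``point`` (voxel-space distance, lex tie-break)."""
    vox = skel.voxels()
    if len(vox) == 0:
        raise ValueError("skeleton is empty")
    p = np.asarray(point, dtype=float)
    d2 = ((vox - p) ** 2).sum(axis=1)
    order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], d2))
    best = vox[order[0]]
    return tuple(int(v) for v in best), float(np.sqrt(d2[order[0]]))


def bfs_depth_map(skel: SkeletonMask, seed, connectivity: str = "faces+edges+corners") -> DepthMap:
    """Breadth-first search over the skeleton from the seed voxel.

    depth(v) is the length of the shortest connectivity-path from the
    seed to v inside the skeleton; every node is visited exactly once
    (FIFO queue, fixed neighbor order), unreached cells stay -1.
    """
    seed = tuple(int(v) for v in seed)
    values = skel.values
    if not values[seed]:
        near, dist = nearest_skeleton_voxel(skel, seed)
        raise ValueError(
            f"seed {seed} is not a skeleton voxel; nearest skeleton voxel is {near} "
            f"({dist:.2f} voxels away)"
        )
    offs = neighbor_offsets(connectivity)
    depth = np.full(values.shape, -1, dtype=np.int32)
    depth[seed] = 0
    queue = deque([seed])
    shape = values.shape
    while queue:
        cur = queue.popleft()
        d = depth[cur] + 1
        for off in offs:
            nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]
                    and values[nb] and depth[nb] < 0):
                depth[nb] = d
                queue.append(nb)
    return DepthMap(values=depth, seed=seed, connectivity=connectivity)


def best_path(dmap: DepthMap, goal) -> BestPath:
    """Backtrack from the goal to the seed along strictly decreasing depth.

    From the goal the walk repeatedly advances to a neighbor whose depth
    is exactly one less than the current depth (lexicographically
    smallest offset on ties) until depth 0 is reached, then returns the
    path ordered seed-first. Spurious skeleton branches cannot appear on
    the result: a branch not containing the goal is never entered by a
    strictly descending walk that starts at the goal.
    """
    goal = tuple(int(v) for v in goal)
    values = dmap.values
    d = int(values[goal])
    if d < 0:
        raise ValueError(f"goal {goal} is unreached (depth -1); pick a goal on the skeleton")
    offs = neighbor_offsets(dmap.connectivity)
    shape = values.shape
    rev = [goal]
    cur = goal
    while d > 0:
        for off in offs:
            nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]
                    and values[nb] == d - 1):
                cur = nb
                d -= 1
                rev.append(cur)
                break
        else:  # cannot happen on a well-formed BFS map
            raise RuntimeError(f"no neighbor with depth {d - 1} next to {cur}")
    pts = np.asarray(rev[::-1], dtype=np.int64)
    depths = np.arange(len(pts), dtype=np.int32)
    return BestPath(points=pts, depths=depths)
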