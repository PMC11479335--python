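"""Synthetic vascular phantoms with exact ground truth.

A phantom is a binary volume rasterized from a tree of cubic Bezier
branches with linearly tapering radii. Because the generating splines
are known analytically, every phantom ships with dense ground-truth
centerline points, per-point radii, and per-branch arc lengths, so
centerline extraction can be validated without manual annotation.

The generator emulates peripheral-artery trees: a root vessel entering
the volume, binary bifurcations with daughter radii reduced to 80% of
the parent, mild tortuosity from seeded control-point jitter. It does
not simulate image intensities, noise, or partial-volume effects — the
masks are clean, which is the regime a segmented input represents.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume_io import VoxelGrid

__all__ = ["BezierBranch", "SplineTree", "Phantom", "generate_spline_tree",
           "rasterize_tree", "phantom_gallery", "GALLERY_SPACING", "GALLERY_RADIUS_RANGE"]

# study conditions for the shipped 10-phantom gallery
GALLERY_SPACING = (1.0, 1.0, 1.0)     # mm, isotropic
GALLERY_RADIUS_RANGE = (2.0, 5.0)     # mm, root start down to terminal minimum
_CHILD_RADIUS_FACTOR = 0.8            # daughter start radius vs parent end radius
_BRANCH_TAPER = 0.85                  # end radius vs start radius within a branch
_BRANCH_ANGLE_DEG = (25.0, 40.0)      # bifurcation half-angle range


@dataclass
class BezierBranch:
    """One cubic Bezier segment of the tree, physical mm coordinates."""

    control: np.ndarray               # (4, 3) control points
    r_start: float
    r_end: float
    parent: int                       # -1 for the root
    t_parent: float = 1.0             # parameter on the parent curve where attached

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        if self.control.shape != (4, 3):
            raise ValueError("a cubic Bezier branch needs exactly 4 control points")
        if self.r_start <= 0 or self.r_end <= 0:
            raise ValueError("branch radii must be positive")

    def point(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        p0, p1, p2, p3 = self.control
        u = 1.0 - t
        return u**3 * p0 + 3 * u**2 * t * p1 + 3 * u * t**2 * p2 + t**3 * p3

    def tangent(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        p0, p1, p2, p3 = self.control
        u = 1.0 - t
        return 3 * u**2 * (p1 - p0) + 6 * u * t * (p2 - p1) + 3 * t**2 * (p3 - p2)

    def radius(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self.r_start + (self.r_end - self.r_start) * t

    def arc_length(self, order: int = 64) -> float:
        """Gauss-Legendre integral of the speed; exact to machine precision here."""
        nodes, weights = np.polynomial.legendre.leggauss(order)
        t = 0.5 * (nodes + 1.0)
        speed = np.linalg.norm(self.tangent(t), axis=1)
        return float(0.5 * np.sum(weights * speed))


@dataclass
class SplineTree:
    """Connected, acyclic collection of Bezier branches."""

    branches: list[BezierBranch]
    seed: int

    def children_of(self, i: int) -> list[int]:
        return [j for j, b in enumerate(self.branches) if b.parent == i]

    def leaves(self) -> list[int]:
        have_child = {b.parent for b in self.branches}
        return [i for i in range(len(self.branches)) if i not in have_child]

    def n_bifurcations(self) -> int:
        from collections import Counter

        counts = Counter(b.parent for b in self.branches if b.parent >= 0)
        return sum(1 for v in counts.values() if v >= 2)

    def root_to_leaf(self, leaf: int) -> list[int]:
        chain = [leaf]
        while self.branches[chain[-1]].parent >= 0:
            chain.append(self.branches[chain[-1]].parent)
        return chain[::-1]

    def translate(self, offset: np.ndarray) -> "SplineTree":
        moved = [BezierBranch(b.control + offset, b.r_start, b.r_end, b.parent, b.t_parent)
                 for b in self.branches]
        return SplineTree(branches=moved, seed=self.seed)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, helper))
    return u, np.cross(d, u)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1.0 - np.cos(angle)))


def _make_branch(rng, start, direction, length, r_start, r_end, tortuosity, parent) -> BezierBranch:
    d = _unit(np.asarray(direction, dtype=float))
    u, w = _perp_basis(d)

    def jitter(scale):
        a, b = rng.normal(0.0, scale, size=2)
        return a * u + b * w

    p0 = np.asarray(start, dtype=float)
    p1 = p0 + (length / 3.0) * d + jitter(tortuosity * length / 3.0)
    p3 = p0 + length * d + jitter(tortuosity * length / 2.0)
    d_end = _unit(d + (tortuosity * np.linalg.norm(rng.normal(0.0, 1.0, 2))) * _unit(jitter(1.0))
                  if tortuosity > 0 else d)
    p2 = p3 - (length / 3.0) * d_end
    return BezierBranch(np.stack([p0, p1, p2, p3]), r_start, r_end, parent)


def generate_spline_tree(n_bifurcations: int = 2,
                         extent=(64.0, 64.0, 64.0),
                         radius_range=GALLERY_RADIUS_RANGE,
                         tortuosity: float = 0.12,
                         seed: int = 0) -> SplineTree:
    """Seeded random binary tree of cubic Bezier branches.

    Produces exactly ``n_bifurcations`` binary branch points and
    ``n_bifurcations + 1`` terminal branches. The root starts at the max
    radius and every branch tapers linearly; daughters start at 80% of
    the parent's end radius, clamped at the minimum radius. Identical
    seeds give bit-identical control points.
    """
    if n_bifurcations < 0:
        raise ValueError("n_bifurcations must be >= 0")
    extent = np.asarray(extent, dtype=float)
    r_min, r_max = (float(radius_range[0]), float(radius_range[1]))
    if r_min <= 0 or r_max < r_min:
        raise ValueError(f"invalid radius_range {radius_range}")
    if 2.0 * r_max >= extent.min():
        raise ValueError(f"max radius {r_max} mm does not fit the extent {tuple(extent)}")
    rng = np.random.default_rng(seed)

    root_len = 0.42 * float(extent.min())
    start = extent * np.array([0.12, 0.5, 0.5])
    direction = _unit(np.array([1.0, 0.0, 0.0]) + rng.normal(0.0, 0.15, 3))
    root = _make_branch(rng, start, direction, root_len, r_max,
                        max(r_min, r_max * _BRANCH_TAPER), tortuosity, parent=-1)
    branches = [root]
    frontier = [0]  # leaves eligible to bifurcate, shallowest first
    for _ in range(n_bifurcations):
        parent_idx = frontier.pop(0)
        parent = branches[parent_idx]
        p_end = parent.point(1.0)[0]
        tang = _unit(parent.tangent(1.0)[0])
        axis = _unit(_perp_basis(tang)[0] + rng.normal(0.0, 0.3, 3))
        half = np.deg2rad(rng.uniform(*_BRANCH_ANGLE_DEG))
        child_len = 0.62 * np.linalg.norm(parent.control[3] - parent.control[0])
        child_r0 = max(r_min, parent.r_end * _CHILD_RADIUS_FACTOR)
        child_r1 = max(r_min, child_r0 * _BRANCH_TAPER)
        for sign in (+1.0, -1.0):
            d_child = _unit(_rotate(tang, axis, sign * half))
            child = _make_branch(rng, p_end, d_child, child_len, child_r0, child_r1,
                                 tortuosity, parent=parent_idx)
            branches.append(child)
            frontier.append(len(branches) - 1)
    return SplineTree(branches=branches, seed=int(seed))


@dataclass
class Phantom:
    """Rasterized tree plus exact ground truth in the grid frame.

    ``truth_points`` holds per-branch dense centerline samples in
    physical mm (voxel index * spacing); ``truth_lengths`` are the
    analytic branch arc lengths.
    """

    grid: VoxelGrid
    tree: SplineTree
    truth_points: list[np.ndarray]
    truth_radii: list[np.ndarray]
    truth_lengths: list[float]

    @property
    def total_length(self) -> float:
        return float(sum(self.truth_lengths))

    def all_truth_points(self) -> np.ndarray:
        return np.concatenate(self.truth_points, axis=0)

    def seed_voxel(self) -> tuple[int, int, int]:
        sp = np.asarray(self.grid.spacing)
        return tuple(int(round(c)) for c in self.truth_points[0][0] / sp)

    def leaf_goal_voxels(self) -> list[tuple[int, int, int]]:
        sp = np.asarray(self.grid.spacing)
        out = []
        for leaf in self.tree.leaves():
            out.append(tuple(int(round(c)) for c in self.truth_points[leaf][-1] / sp))
        return out

    def truth_polyline_to_leaf(self, leaf: int) -> np.ndarray:
        """Ordered truth points (mm) from the root start to the leaf end."""
        chain = self.tree.root_to_leaf(leaf)
        return np.concatenate([self.truth_points[i] for i in chain], axis=0)

    def save(self, out_dir) -> None:
        """Volume as NIfTI plus truth CSVs and a JSON manifest."""
        from pathlib import Path

        from .volume_io import save_mask

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_mask(self.grid, out / "phantom.nii.gz")
        import csv

        with open(out / "truth_points.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["branch", "x_mm", "y_mm", "z_mm", "radius_mm"])
            for b, (pts, rads) in enumerate(zip(self.truth_points, self.truth_radii)):
                for p, r in zip(pts, rads):
                    w.writerow([b, repr(float(p[0])), repr(float(p[1])),
                                repr(float(p[2])), repr(float(r))])
        manifest = {
            "seed": self.tree.seed,
            "spacing_mm": list(self.grid.spacing),
            "shape": list(self.grid.shape),
            "n_branches": len(self.tree.branches),
            "n_bifurcations": self.tree.n_bifurcations(),
            "n_terminal_branches": len(self.tree.leaves()),
            "branch_lengths_mm": [float(v) for v in self.truth_lengths],
            "total_length_mm": self.total_length,
            "seed_voxel": list(self.seed_voxel()),
            "goal_voxels": [list(g) for g in self.leaf_goal_voxels()],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _dense_samples(branch: BezierBranch, step_mm: float):
    """Curve samples at <= step_mm arc spacing (uniform in arc length)."""
    length = branch.arc_length()
    t = np.linspace(0.0, 1.0, 4096)
    pts = branch.point(t)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    n = max(2, int(np.ceil(s[-1] / step_mm)) + 1)
    si = np.linspace(0.0, s[-1], n)
    ti = np.interp(si, s, t)
    return branch.point(ti), branch.radius(ti), length


def rasterize_tree(tree: SplineTree, spacing=GALLERY_SPACING, margin: float = 2.0) -> Phantom:
    """Rasterize a spline tree into a binary volume with ground truth.

    A voxel is foreground when its center lies within the local radius
    of the nearest curve point, evaluated by dense sampling at <=
    min(spacing)/4 arc steps. Truth points are sampled at <=
    min(spacing)/2 steps; branch lengths come from analytic quadrature.
    """
    sp = np.asarray(spacing, dtype=float)
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    min_sp = float(sp.min())
    fine = [
        _dense_samples(b, step_mm=min_sp / 4.0) for b in tree.branches
    ]
    min_radius = min(float(np.min(r)) for _, r, _ in fine)
    if min_radius < min_sp:
        warnings.warn(
            f"tube radius {min_radius:.2f} mm below voxel spacing {min_sp} mm; "
            "enforcing a minimum one-voxel tube"
        )
    all_pts = np.concatenate([p for p, _, _ in fine], axis=0)
    all_r = np.concatenate([r for _, r, _ in fine])
    lo = (all_pts - all_r[:, None]).min(axis=0) - margin
    offset = -lo
    shape = tuple(int(np.ceil(v)) + 1
                  for v in ((all_pts + all_r[:, None]).max(axis=0) + margin + offset) / sp)
    values = np.zeros(shape, dtype=np.uint8)
    for pts, rads, _ in fine:
        for c, r in zip(pts + offset, np.maximum(rads, min_sp)):
            lo_i = np.maximum(0, np.floor((c - r) / sp).astype(int))
            hi_i = np.minimum(np.asarray(shape) - 1, np.ceil((c + r) / sp).astype(int))
            gx, gy, gz = np.ogrid[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1]
            d2 = ((gx * sp[0] - c[0]) ** 2 + (gy * sp[1] - c[1]) ** 2
                  + (gz * sp[2] - c[2]) ** 2)
            region = values[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1]
            region[d2 <= r * r] = 1

    shifted = tree.translate(offset)
    truth_points, truth_radii, truth_lengths = [], [], []
    for b in shifted.branches:
        pts, rads, length = _dense_samples(b, step_mm=min_sp / 2.0)
        truth_points.append(pts)
        truth_radii.append(rads)
        truth_lengths.append(length)
    grid = VoxelGrid(values, tuple(float(s) for s in sp))
    return Phantom(grid=grid, tree=shifted, truth_points=truth_points,
                   truth_radii=truth_radii, truth_lengths=truth_lengths)


def phantom_gallery(n: int = 10, base_seed: int = 0, spacing=GALLERY_SPACING):
    """The shipped gallery: ``n`` seeded phantoms at the study conditions.

    Spacing 1 mm isotropic, radii 2-5 mm, one to three bifurcations per
    phantom, mild tortuosity — a programmatic stand-in for a set of ten
    hand-authored synthetic vessel volumes.
    """
    out = []
    for i in range(n):
        tree = generate_spline_tree(
            n_bifurcations=(i % 3) + 1,
            extent=(64.0, 64.0, 64.0),
            radius_range=GALLERY_RADIUS_RANGE,
            tortuosity=0.12,
            seed=base_seed * 1000 + i,
        )
        out.append(rasterize_tree(tree, spacing=spacing))
    return out
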