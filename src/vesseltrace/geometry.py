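"""Geometric measurements on extracted vessel paths.

Length is the sum of spacing-weighted Euclidean distances between
subsequent path points. Radii are read from the distance map (the
inscribed-sphere radius at each point). Curvature uses the circumradius
of point triples on an arc-length-resampled path: three points spaced
``window`` steps apart define a circle, and curvature is the reciprocal
of its radius (0 for collinear triples).

Voxel paths are jagged: an 8- or 26-connected chain systematically
overestimates the length of a smooth curve by up to a few percent
because every step is forced onto lattice directions. ``smooth_path``
applies a small moving average (endpoints pinned) to suppress that
staircase bias before measurement; the pipeline reports both the raw and
the smoothed length and labels which path they came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance_map import DistanceMap

__all__ = [
    "GeometryReport",
    "path_length",
    "radius_profile",
    "curvature_profile",
    "smooth_path",
    "resample_path",
]


@dataclass
class GeometryReport:
    """Per-goal geometry: length plus radius/curvature profiles (mm units)."""

    length_mm: float
    radius_profile_mm: np.ndarray
    curvature_profile_per_mm: np.ndarray
    length_source: str = "best_path"
    raw_length_mm: float | None = None

    def summary(self) -> dict:
        r = np.asarray(self.radius_profile_mm, dtype=float)
        return {
            "length_mm": float(self.length_mm),
            "raw_length_mm": None if self.raw_length_mm is None else float(self.raw_length_mm),
            "length_source": self.length_source,
            "mean_radius_mm": float(r.mean()),
            "min_radius_mm": float(r.min()),
            "max_radius_mm": float(r.max()),
        }


def _phys(points, spacing) -> np.ndarray:
    return np.asarray(points, dtype=float) * np.asarray(spacing, dtype=float)


def path_length(points, spacing=(1.0, 1.0, 1.0)) -> float:
    """Sum of Euclidean distances between subsequent points, in mm."""
    pts = _phys(points, spacing)
    if len(pts) < 2:
        raise ValueError("path length needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def radius_profile(points, dmap: DistanceMap) -> np.ndarray:
    """Distance-map value (inscribed-sphere radius, mm) at each path point."""
    pts = np.asarray(points, dtype=np.int64)
    vals = dmap.values[pts[:, 0], pts[:, 1], pts[:, 2]]
    if np.any(vals <= 0):
        bad = pts[np.argmax(vals <= 0)]
        raise ValueError(f"path point {tuple(bad)} lies on background")
    return vals.astype(float)


def smooth_path(points, spacing=(1.0, 1.0, 1.0), window: int = 5) -> np.ndarray:
    """Moving-average smoothing of a polyline in physical coordinates.

    The first and last points are pinned so endpoints (seed/goal) are
    preserved; interior points are averaged over a centered window
    truncated at the ends. Returns physical-mm coordinates.
    """
    pts = _phys(points, spacing)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if len(pts) <= 2 or window == 1:
        return pts
    half = window // 2
    out = pts.copy()
    for i in range(1, len(pts) - 1):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def resample_path(points_mm: np.ndarray, step_mm: float = 1.0) -> np.ndarray:
    """Resample a physical-coordinate polyline to uniform arc-length steps."""
    pts = np.asarray(points_mm, dtype=float)
    if len(pts) < 2:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate(([True], seg > 0))
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("path has no extent after removing repeated points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    n = max(2, int(np.ceil(s[-1] / step_mm)) + 1)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, a]) for a in range(3)])


def _circumradius_curvature(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Curvature = 1 / circumradius of triangle (a, b, c); 0 if collinear."""
    ab, ac, bc = b - a, c - a, c - b
    la, lb, lc = np.linalg.norm(bc), np.linalg.norm(ac), np.linalg.norm(ab)
    cross = np.cross(ab, ac)
    area2 = np.linalg.norm(cross)  # = 2 * triangle area
    if area2 < 1e-12 or min(la, lb, lc) < 1e-12:
        return 0.0
    return float(2.0 * area2 / (la * lb * lc))


def curvature_profile(points, spacing=(1.0, 1.0, 1.0), window: int = 3,
                      step_mm: float = 1.0) -> np.ndarray:
    """Discrete curvature (1/mm) along the path.

    The path is resampled to uniform ``step_mm`` arc steps; at each
    interior sample the circle through the samples ``window`` steps
    before and after gives the local curvature. Straight paths return 0
    everywhere.
    """
    pts = _phys(points, spacing)
    if len(np.unique(pts.round(9), axis=0)) < 3:
        raise ValueError("curvature needs at least 3 distinct points")
    rs = resample_path(pts, step_mm=step_mm)
    if len(rs) < 3:
        raise ValueError("path too short for curvature at this resampling step")
    w = max(1, min(window, (len(rs) - 1) // 2))
    out = []
    for i in range(w, len(rs) - w):
        out.append(_circumradius_curvature(rs[i - w], rs[i], rs[i + w]))
    return np.asarray(out, dtype=float)
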