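"""Volume and point-set I/O with explicit coordinate conventions.

All public functions use 0-based voxel indices in axis order (x, y, z),
matching the order in which the raster is stored in memory. Physical
coordinates are voxel index times per-axis spacing in millimetres.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "PointSet",
    "load_mask",
    "save_mask",
    "save_centerline",
    "load_centerline",
]


@dataclass
class VoxelGrid:
    """A binary 3D lattice with physical voxel spacing.

    Parameters
    ----------
    values : ndarray of {0, 1}, shape (size_x, size_y, size_z)
        Foreground (vessel) voxels are 1, background 0.
    spacing : tuple of 3 floats
        Physical step per axis in mm; all components must be positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D lattice, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"every shape component must be >= 1, got {self.values.shape}")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("grid values must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive components, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def foreground_count(self) -> int:
        return int(self.values.sum())


@dataclass
class PointSet:
    """Ordered list of points tagged with their coordinate frame."""

    points: np.ndarray
    frame: str = "voxel"  # {"voxel", "physical-mm"}

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if np.any(~np.isfinite(self.points)):
            raise ValueError("points contain NaN/inf coordinates")
        if self.frame not in ("voxel", "physical-mm"):
            raise ValueError(f"unknown frame {self.frame!r}")

    def __len__(self) -> int:
        return len(self.points)


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def load_mask(path: str | Path) -> VoxelGrid:
    """Read a 3D raster and binarize it (nonzero -> 1).

    Spacing is taken from the header zooms; if the header carries no
    spacing a 1.0 mm isotropic default is used with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D raster, got ndim={data.ndim} in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        warnings.warn(f"{path}: header lacks voxel spacing; defaulting to 1.0 mm isotropic")
        zooms = (1.0, 1.0, 1.0)
    return VoxelGrid((data != 0).astype(np.uint8), tuple(float(z) for z in zooms))


def save_mask(grid: VoxelGrid, path: str | Path) -> None:
    """Write a VoxelGrid as NIfTI; round-trips through :func:`load_mask`."""
    path = Path(path)
    img = nib.Nifti1Image(grid.values.astype(np.uint8), _affine_from_spacing(grid.spacing))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def save_centerline(path_obj, file: str | Path) -> None:
    """Write an ordered centerline as CSV (index, p, q, r, radius_mm)."""
    points = np.asarray(path_obj.points)
    radii = np.asarray(path_obj.radii, dtype=float)
    if len(points) == 0:
        raise ValueError("cannot save an empty centerline")
    with open(file, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "p", "q", "r", "radius_mm"])
        for i, (pt, rad) in enumerate(zip(points, radii)):
            writer.writerow([i, int(pt[0]), int(pt[1]), int(pt[2]), repr(float(rad))])


def load_centerline(file: str | Path):
    """Read a centerline CSV written by :func:`save_centerline`."""
    from .tracking import CenterPath

    points, radii = [], []
    with open(file, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            points.append((int(row["p"]), int(row["q"]), int(row["r"])))
            radii.append(float(row["radius_mm"]))
    if not points:
        raise ValueError(f"{file}: no centerline records")
    return CenterPath(points=np.asarray(points, dtype=np.int64), radii=np.asarray(radii))
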