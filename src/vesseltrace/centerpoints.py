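"""Candidate centerpoint extraction by iterative maximum selection.

Working on a copy of the distance map, the global maximum value and its
index (i,j,k) are recorded as a centerpoint, then every voxel (x,y,z)
with

    (i-x)^2 + (j-y)^2 + (k-z)^2 <= r^2,   r = dt(i,j,k),

is zeroed (in mm mode the offsets are spacing-weighted so the removal
region is a physical ball). The loop repeats until the working copy is
identically zero, producing a list of inscribed-sphere centers ordered
by non-increasing radius that covers the whole foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance_map import DistanceMap

__all__ = ["Centerpoint", "CenterpointList", "extract_centerpoints", "snap_to_centerpoint"]


@dataclass(frozen=True)
class Centerpoint:
    """An inscribed-sphere center: voxel index plus the map value there."""

    index: tuple[int, int, int]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"centerpoint radius must be positive, got {self.radius}")


@dataclass
class CenterpointList:
    """Extraction-ordered centerpoints; radii are non-increasing."""

    centerpoints: list[Centerpoint] = field(default_factory=list)
    units: str = "mm"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __len__(self) -> int:
        return len(self.centerpoints)

    def __iter__(self):
        return iter(self.centerpoints)

    def __getitem__(self, i):
        return self.centerpoints[i]

    def indices(self) -> np.ndarray:
        return np.asarray([c.index for c in self.centerpoints], dtype=np.int64)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["i", "j", "k", "radius"])
            for c in self.centerpoints:
                w.writerow([*c.index, repr(c.radius)])


def _zero_ball(work: np.ndarray, center: tuple[int, int, int], radius: float,
               scale: np.ndarray) -> None:
    """Zero every voxel whose (scaled) offset from center lies in the closed ball."""
    lo, hi = [], []
    for a in range(3):
        extent = int(np.floor(radius / scale[a]))
        lo.append(max(0, center[a] - extent))
        hi.append(min(work.shape[a] - 1, center[a] + extent))
    if any(l > h for l, h in zip(lo, hi)):
        work[center] = 0.0
        return
    gx, gy, gz = np.ogrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    d2 = (((gx - center[0]) * scale[0]) ** 2
          + ((gy - center[1]) * scale[1]) ** 2
          + ((gz - center[2]) * scale[2]) ** 2)
    region = work[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    region[d2 <= radius ** 2] = 0.0
    work[center] = 0.0


def extract_centerpoints(dmap: DistanceMap) -> CenterpointList:
    """Repeated argmax + sphere removal on a working copy of the map.

    The input map is never mutated. Ties at the maximum are broken by the
    lexicographically smallest (i,j,k), which makes the output
    deterministic. Returns an empty list for an all-zero map.
    """
    work = dmap.values.copy()
    scale = np.asarray(dmap.spacing if dmap.units == "mm" else (1.0, 1.0, 1.0))
    out = CenterpointList(units=dmap.units, spacing=dmap.spacing)
    while True:
        flat = int(np.argmax(work))  # first occurrence in C order = lexicographic min
        value = float(work.flat[flat])
        if value <= 0.0:
            break
        idx = tuple(int(v) for v in np.unravel_index(flat, work.shape))
        out.centerpoints.append(Centerpoint(index=idx, radius=value))
        _zero_ball(work, idx, value, scale)
    return out


def snap_to_centerpoint(point, cplist: CenterpointList,
                        spacing: tuple[float, float, float] | None = None) -> Centerpoint:
    """Nearest centerpoint to a voxel coordinate; earlier list position wins ties.

    Distances are spacing-weighted when ``spacing`` is given (defaults to
    the list's own spacing), so anisotropic grids snap in physical space.
    """
    if len(cplist) == 0:
        raise ValueError("cannot snap to an empty centerpoint list")
    sp = np.asarray(spacing if spacing is not None else cplist.spacing, dtype=float)
    p = np.asarray(point, dtype=float)
    idx = cplist.indices().astype(float)
    d2 = (((idx - p) * sp) ** 2).sum(axis=1)
    best = int(np.argmin(d2))  # argmin returns the first minimum: earlier wins
    return cplist[best]
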