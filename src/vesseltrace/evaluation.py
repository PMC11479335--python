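"""Accuracy metrics for extracted centerlines against ground truth.

The centerline metric is the directed mean nearest-neighbor distance:
each extracted point is matched to its nearest ground-truth point in
physical coordinates and the distances are averaged. Length accuracy is
the absolute difference between estimated and true length in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ErrorSummary", "mean_centerline_error", "length_error", "resample_polyline"]


@dataclass
class ErrorSummary:
    """Per-dataset mean errors with the overall mean and spread."""

    dataset_errors_mm: list[float]
    length_errors_mm: list[float] = field(default_factory=list)

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.dataset_errors_mm))

    @property
    def std_mm(self) -> float:
        return float(np.std(self.dataset_errors_mm))

    def to_frame(self):
        import pandas as pd

        rows = [{"dataset": i + 1, "mean_error_mm": e}
                for i, e in enumerate(self.dataset_errors_mm)]
        df = pd.DataFrame(rows)
        if self.length_errors_mm:
            df["length_error_mm"] = self.length_errors_mm
        footer = {"dataset": "Mean ± STD",
                  "mean_error_mm": f"{self.mean_mm:.3f} ± {self.std_mm:.3f}"}
        if self.length_errors_mm:
            footer["length_error_mm"] = (
                f"{np.mean(self.length_errors_mm):.3f} ± {np.std(self.length_errors_mm):.3f}"
            )
        return pd.concat([df, pd.DataFrame([footer])], ignore_index=True)


def resample_polyline(points_mm: np.ndarray, step_mm: float = 0.25) -> np.ndarray:
    """Densify an ordered polyline to at most ``step_mm`` arc steps.

    Used on ground-truth polylines before matching so that the finite
    sampling of the truth does not inflate the reported error.
    """
    pts = np.asarray(points_mm, dtype=float)
    if len(pts) < 2:
        return pts
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(seg / step_mm)))
        for t in np.linspace(0.0, 1.0, n + 1)[1:]:
            out.append(a + t * (b - a))
    return np.asarray(out)


def mean_centerline_error(extracted_mm, truth_mm, symmetric: bool = False) -> float:
    """Directed mean distance from extracted points to nearest truth points (mm).

    With ``symmetric=True`` the average of both matching directions is
    returned instead.
    """
    ext = np.atleast_2d(np.asarray(extracted_mm, dtype=float))
    tru = np.atleast_2d(np.asarray(truth_mm, dtype=float))
    if len(ext) == 0 or len(tru) == 0:
        raise ValueError("both point lists must be nonempty")
    d_et = cKDTree(tru).query(ext)[0]
    if not symmetric:
        return float(np.mean(d_et))
    d_te = cKDTree(ext).query(tru)[0]
    return float(0.5 * (np.mean(d_et) + np.mean(d_te)))


def length_error(estimated_mm: float, truth_mm: float) -> float:
    """Absolute length error |estimated - truth| in mm."""
    if estimated_mm < 0 or truth_mm < 0:
        raise ValueError("lengths must be nonnegative")
    return abs(float(estimated_mm) - float(truth_mm))
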