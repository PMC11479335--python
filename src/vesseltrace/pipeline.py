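"""End-to-end orchestration: simulate, extract, evaluate.

``extract_tree`` is the library entry point: mask in, centerline tree
and geometry out, with a machine-readable stage log. ``run_extract``,
``run_simulate`` and ``run_evaluate`` wrap it with file I/O so every
stage can also be driven from serialized artifacts on disk.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as geom
from .centerpoints import extract_centerpoints, snap_to_centerpoint
from .distance_map import euclidean_distance_map
from .evaluation import ErrorSummary, length_error, mean_centerline_error, resample_polyline
from .skeleton_paths import best_path, bfs_depth_map, extract_skeleton, nearest_skeleton_voxel
from .synthetic_data import generate_spline_tree, rasterize_tree
from .tracking import CenterlineMap, merge_into_tree, track_centerline
from .volume_io import VoxelGrid, load_mask, save_centerline

__all__ = ["RunConfig", "ExtractionResult", "extract_tree", "run_extract",
           "run_simulate", "run_evaluate"]


@dataclass
class RunConfig:
    """Configuration shared by the pipeline entry points."""

    input_path: str | None = None
    seed_point: tuple[int, int, int] | None = None
    goal_points: list[tuple[int, int, int]] = field(default_factory=list)
    units: str = "mm"
    connectivity: str = "faces+edges+corners"
    curvature_window: int = 3
    length_source: str = "best_path"   # or "tracked"
    out_dir: str | None = None
    random_seed: int = 0
    n_bifurcations: int = 2
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    verbosity: int = 1


@dataclass
class ExtractionResult:
    """Everything one extraction run produces."""

    goals: list[dict]                  # per goal: paths, geometry, snaps
    centerline_map: CenterlineMap
    log: list[dict]
    distance_map: object | None = None
    centerpoints: object | None = None


def _validate_points(grid: VoxelGrid, seed_point, goal_points) -> None:
    if not goal_points:
        raise ValueError("at least one goal point is required")
    for name, pt in [("seed", seed_point)] + [(f"goal[{i}]", g) for i, g in enumerate(goal_points)]:
        pt = tuple(int(v) for v in pt)
        if not all(0 <= pt[a] < grid.shape[a] for a in range(3)):
            raise ValueError(f"{name} {pt} lies outside the volume of shape {grid.shape}")
        if not grid.values[pt]:
            raise ValueError(f"{name} {pt} lies on background; pick a vessel voxel")


def extract_tree(grid: VoxelGrid, seed_point, goal_points, *, units: str = "mm",
                 connectivity: str = "faces+edges+corners", curvature_window: int = 3,
                 length_source: str = "best_path") -> ExtractionResult:
    """Full centerline pipeline on an in-memory mask.

    Stages: distance map -> skeleton -> centerpoints -> snap seed/goals
    -> BFS depth map -> per-goal best path -> tracking -> tree merge ->
    geometry. Seed and goal coordinates are snapped to extracted
    centerpoints (and, for the BFS, to the nearest skeleton voxel); the
    snap distances are recorded in the stage log.
    """
    if length_source not in ("best_path", "tracked"):
        raise ValueError(f"length_source must be 'best_path' or 'tracked', got {length_source!r}")
    log: list[dict] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        out = fn()
        log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 4)})
        return out

    _validate_points(grid, seed_point, goal_points)
    dmap = stage("distance_map", lambda: euclidean_distance_map(grid, units=units))
    skel = stage("skeleton", lambda: extract_skeleton(grid))
    cpoints = stage("centerpoints", lambda: extract_centerpoints(dmap))

    seed_cp = snap_to_centerpoint(seed_point, cpoints)
    seed_skel, seed_snap = nearest_skeleton_voxel(skel, seed_cp.index)
    log.append({"stage": "snap_seed", "centerpoint": list(seed_cp.index),
                "skeleton_voxel": list(seed_skel), "skeleton_snap_voxels": round(seed_snap, 3)})
    depth = stage("bfs_depth_map", lambda: bfs_depth_map(skel, seed_skel, connectivity))

    cmap = CenterlineMap.zeros(grid.shape)
    spacing = grid.spacing
    goals_out = []
    for gi, gpt in enumerate(goal_points):
        goal_cp = snap_to_centerpoint(gpt, cpoints)
        goal_skel, goal_snap = nearest_skeleton_voxel(skel, goal_cp.index)
        bp = best_path(depth, goal_skel)
        cpath = track_centerline(dmap, bp, seed_cp, goal_cp)
        cmap, merge_info = merge_into_tree(cpath, cmap)

        length_pts = bp.points if length_source == "best_path" else cpath.points
        raw_len = geom.path_length(length_pts, spacing)
        smooth = geom.smooth_path(length_pts, spacing)
        smooth_len = float(np.linalg.norm(np.diff(smooth, axis=0), axis=1).sum())
        report = geom.GeometryReport(
            length_mm=smooth_len,
            radius_profile_mm=geom.radius_profile(cpath.points, dmap),
            curvature_profile_per_mm=geom.curvature_profile(
                cpath.points, spacing, window=curvature_window),
            length_source=length_source,
            raw_length_mm=raw_len,
        )
        goals_out.append({
            "goal_input": tuple(int(v) for v in gpt),
            "goal_centerpoint": goal_cp.index,
            "goal_skeleton_voxel": goal_skel,
            "skeleton_snap_voxels": round(goal_snap, 3),
            "best_path": bp,
            "center_path": cpath,
            "geometry": report,
            "merge_junction": merge_info["junction"],
            "n_merged_voxels": len(merge_info["added"]),
        })
        log.append({"stage": f"goal_{gi}", "path_points": len(cpath),
                    "best_path_points": len(bp), "length_mm": round(report.length_mm, 3)})

    return ExtractionResult(goals=goals_out, centerline_map=cmap, log=log,
                            distance_map=dmap, centerpoints=cpoints)


def run_extract(config: RunConfig) -> ExtractionResult:
    """File-based extraction: read mask, run the pipeline, write artifacts."""
    if config.input_path is None or config.seed_point is None:
        raise ValueError("run_extract needs input_path and seed_point")
    grid = load_mask(config.input_path)
    result = extract_tree(
        grid, config.seed_point, config.goal_points, units=config.units,
        connectivity=config.connectivity, curvature_window=config.curvature_window,
        length_source=config.length_source,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import nibabel as nib

        aff = np.diag(list(grid.spacing) + [1.0])
        nib.save(nib.Nifti1Image(result.centerline_map.values, aff),
                 str(out / "centerline_map.nii.gz"))
        summary = {"goals": [], "log": result.log}
        for gi, g in enumerate(result.goals):
            save_centerline(g["center_path"], out / f"centerline_goal{gi}.csv")
            summary["goals"].append({
                "goal_input": list(g["goal_input"]),
                "goal_centerpoint": list(g["goal_centerpoint"]),
                "skeleton_snap_voxels": g["skeleton_snap_voxels"],
                **g["geometry"].summary(),
            })
        with open(out / "geometry.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return result


def run_simulate(config: RunConfig):
    """Generate one phantom from the config seed and write its files."""
    tree = generate_spline_tree(n_bifurcations=config.n_bifurcations,
                                seed=config.random_seed)
    phantom = rasterize_tree(tree, spacing=config.spacing)
    if config.out_dir:
        phantom.save(config.out_dir)
    return phantom


def evaluate_extraction(result: ExtractionResult, phantom) -> dict:
    """Compare one extraction against its phantom's ground truth.

    Centerline error: directed mean distance from tracked points to the
    densified truth polylines. Length error: per traced goal, the best
    path length against the analytic arc length of the truth segment
    between the truth points nearest to the traced endpoints.
    """
    sp = np.asarray(phantom.grid.spacing)
    truth_all = resample_polyline_set(phantom)
    extracted = np.concatenate(
        [g["center_path"].points.astype(float) * sp for g in result.goals], axis=0)
    cl_err = mean_centerline_error(extracted, truth_all)

    per_goal = []
    leaves = phantom.tree.leaves()
    for g in result.goals:
        goal_mm = np.asarray(g["goal_centerpoint"], float) * sp
        # pair the traced goal with the nearest leaf's truth polyline
        leaf = min(leaves, key=lambda b: float(
            np.min(np.linalg.norm(phantom.truth_points[b] - goal_mm, axis=1))))
        poly = phantom.truth_polyline_to_leaf(leaf)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        s = np.concatenate(([0.0], np.cumsum(seg)))
        # clip the truth at the endpoints of the polyline that was measured
        measured = (g["best_path"].points if g["geometry"].length_source == "best_path"
                    else g["center_path"].points)
        start_mm = measured[0].astype(float) * sp
        end_mm = measured[-1].astype(float) * sp
        i0 = int(np.argmin(np.linalg.norm(poly - start_mm, axis=1)))
        i1 = int(np.argmin(np.linalg.norm(poly - end_mm, axis=1)))
        truth_len = abs(float(s[i1] - s[i0]))
        est_len = g["geometry"].length_mm
        per_goal.append({
            "leaf_branch": leaf,
            "estimated_length_mm": est_len,
            "truth_length_mm": truth_len,
            "length_error_mm": length_error(est_len, truth_len),
            "length_error_pct": (100.0 * length_error(est_len, truth_len) / truth_len
                                 if truth_len > 0 else float("nan")),
        })
    return {"mean_centerline_error_mm": cl_err, "goals": per_goal}


def resample_polyline_set(phantom, step_mm: float = 0.25) -> np.ndarray:
    """All truth branches of a phantom, densified and concatenated (mm)."""
    return np.concatenate(
        [resample_polyline(p, step_mm=step_mm) for p in phantom.truth_points], axis=0)


def run_evaluate(pred_dirs, truth_dirs, out_path=None) -> ErrorSummary:
    """Paired file-based evaluation across datasets.

    Each prediction directory must hold ``centerline_goal*.csv`` and
    ``geometry.json`` from :func:`run_extract`; each truth directory the
    ``truth_points.csv``/``manifest.json`` written by a phantom.
    """
    pred_dirs, truth_dirs = list(pred_dirs), list(truth_dirs)
    if len(pred_dirs) != len(truth_dirs):
        raise ValueError(
            f"got {len(pred_dirs)} prediction dirs but {len(truth_dirs)} truth dirs")
    import csv

    dataset_errors = []
    for pd_, td in zip(pred_dirs, truth_dirs):
        pd_, td = Path(pd_), Path(td)
        missing = [str(p) for p in (td / "truth_points.csv", pd_ / "geometry.json")
                   if not p.exists()]
        cl_files = sorted(pd_.glob("centerline_goal*.csv"))
        if not cl_files:
            missing.append(str(pd_ / "centerline_goal*.csv"))
        if missing:
            raise ValueError("missing evaluation inputs: " + ", ".join(missing))
        with open(td / "manifest.json") as fh:
            manifest = json.load(fh)
        sp = np.asarray(manifest["spacing_mm"])
        branches: dict[int, list] = {}
        with open(td / "truth_points.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                branches.setdefault(int(row["branch"]), []).append(
                    (float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])))
        truth = np.concatenate(
            [resample_polyline(np.asarray(v)) for v in branches.values()], axis=0)
        from .volume_io import load_centerline

        ext = np.concatenate(
            [load_centerline(f).points.astype(float) * sp for f in cl_files], axis=0)
        dataset_errors.append(mean_centerline_error(ext, truth))
    summary = ErrorSummary(dataset_errors_mm=dataset_errors)
    if out_path:
        summary.to_frame().to_csv(out_path, index=False)
    return summary
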