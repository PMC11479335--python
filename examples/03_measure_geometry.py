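"""Measure radius and curvature profiles along an extracted centerline.

Uses a gently curved single-branch phantom so the profiles have known
behavior: the radius tapers linearly along the vessel and the curvature
stays small and positive.
"""

import numpy as np

import vesseltrace as vt

phantom = vt.rasterize_tree(
    vt.generate_spline_tree(n_bifurcations=0, tortuosity=0.2, seed=12))
result = vt.extract_tree(phantom.grid, phantom.seed_voxel(), phantom.leaf_goal_voxels())
goal = result.goals[0]

radii = goal["geometry"].radius_profile_mm
curv = goal["geometry"].curvature_profile_per_mm
print(f"tracked points:        {len(goal['center_path'])}")
print(f"radius profile (mm):   first {radii[0]:.2f}  median {np.median(radii):.2f}  "
      f"last {radii[-1]:.2f}")
print(f"curvature (1/mm):      mean {curv.mean():.4f}  max {curv.max():.4f}")
print(f"radius of curvature:   ~{1.0 / max(curv.mean(), 1e-9):.0f} mm (mean)")
# Radii are inscribed-sphere radii from the distance map; curvature is the
# reciprocal circumradius of point triples on the arc-resampled path.
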