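# Methods

This note records the model behind each stage, the parameters that
matter, the numerical choices made where the procedure was genuinely
open, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Input model and coordinate conventions

The input is a segmented binary volume: foreground 1 where vessel lumen
was segmented, background 0 elsewhere, with per-axis voxel spacing in
mm. All public APIs use 0-based voxel indices in the order the raster is
stored, axes named (x, y, z); physical coordinates are index × spacing.
When a volume header carries no spacing, 1 mm isotropic is assumed with
a warning. The pipeline default is mm units throughout, so reported
radii and lengths are physical; voxel units are available for didactic
parity with the unit-spacing definitions.

## Distance transform

The per-voxel distance to the nearest background voxel is computed with
the exact separable Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`), optionally spacing-weighted.
This is mathematically identical to the literal minimization over all
background voxels (the defining form), and the test suite pins that
equivalence voxelwise against a brute-force double loop on random
grids. A grid with no background voxel has an undefined transform;
the default behavior (`pad_border="auto"`) pads such a grid with a
one-voxel zero border and crops the result, treating the volume border
as vessel wall. Padding is deliberately *not* applied when in-grid
background exists, so results match the defining minimization exactly
even where the foreground touches a face; `pad_border=True` forces
border-as-wall semantics when that is the better physical model.
No smoothing is applied to the map: the tracking stage reads raw
inscribed-sphere radii from it.

## Centerpoints

Candidate centerpoints come from repeated maximum selection on a
working copy of the distance map: record the global maximum value and
its index, zero the closed ball of that radius around it (a physical
ball in mm mode — offsets scaled by spacing), repeat until the copy is
identically zero. The ordered list therefore has non-increasing radii
and its balls cover the entire foreground. Ties at the maximum are
broken by the lexicographically smallest index, which fixes determinism
(this is exactly what `numpy.argmax`'s first-occurrence rule yields).
The original map is never mutated; tracking needs live values. Seed and
goal coordinates supplied by the caller are snapped to the nearest
centerpoint (spacing-weighted distance, earlier list position wins
ties) so traces start and end on the medial axis.

## Skeleton, depth map, best path

Skeletonization is delegated to `skimage.morphology.skeletonize`
(Lee-style 3D thinning); the contract relied on — thin, subset of the
foreground, connectivity-preserving — is what the tests check, not a
specific thinning recipe. The BFS depth map and the downhill backtrack
are implemented directly: FIFO queue, each node visited once, neighbor
offsets scanned in a fixed lexicographic order so the map and path are
bit-reproducible. Connectivity is a parameter: 26-adjacency by default
(3D thinning output is generally 26-connected and would fall apart
under 6-adjacency), face-adjacency for the 2D worked example, where
the corner-to-corner depth of a 5×5 all-foreground mask is 8 (the
Manhattan distance). A goal's best path has exactly depth(goal)+1
points and cannot contain a voxel of a skeleton branch that does not
lead to the goal, since depth decreases strictly along the walk.
If a snapped seed or goal is off-skeleton it is moved to the nearest
skeleton voxel and the snap distance is logged.

## Tracking

At the current point a cube of radius r = round(dt / min-spacing) ≥ 1
voxels is built (bounds clamped to the grid), and its six faces are
scanned in a fixed order (x-low, x-high, y-low, y-high, z-low, z-high,
lexicographic within a face) for the voxel with the highest distance
value. Inside a tube this voxel lies on the medial axis roughly one
radius ahead or behind — which is why the plain "does the candidate's
sphere touch the best path?" test is insufficient as a direction
filter: near the seed, a retrograde candidate's sphere touches the path
just as well. The acceptance rule used is therefore *monotone
progress*: the candidate's sphere (its own dt value as radius, physical
units) must contain a best-path voxel with an index strictly beyond the
furthest index any accepted sphere has reached. This single rule
rejects both wrong-branch candidates at bifurcations (their spheres
reach no new path voxels) and backward steps, and it bounds the number
of accepted steps by the best-path length, guaranteeing termination.
Rejected candidates are zeroed on a private working copy (the pristine
map serves radius reporting and later goals); when a cube offers no
acceptable candidate the walk backtracks to the previous accepted
point. Tracking stops when the goal lies within the current sphere,
within one voxel of the current point, or when the swept spheres have
covered the final best-path voxel — without the last condition the walk
stalls near the goal once progress saturates. The goal is appended as
the final point. A generous iteration cap (50·(foreground)^⅓ + 1000
candidate evaluations) guards against pathological masks.

## Tree merging

Per-goal centerlines are merged into a binary centerline map. Each
tracked path is densified to a 26-connected voxel chain (accepted
points are about one radius apart) and walked from its goal end toward
the seed; the walk halts at the first voxel already set, so a shared
trunk is written exactly once and each merge attaches one simple arc.
Before writing, the chain is simplified by a farthest-adjacent
shortcut: from each voxel, jump to the farthest later chain voxel still
26-adjacent. This removes one-voxel zigzags in the raw chain (tracked
paths may wobble laterally by a voxel near bifurcations) that would
otherwise thicken the map to 2×2 locally. The full tracked paths,
with every accepted point, remain available separately; the map is the
thin tree summary.

## Geometry

Length is the sum of spacing-weighted Euclidean distances between
subsequent points of the best path (a flag switches to the tracked
path; outputs label which was used). Raw voxel chains systematically
overestimate smooth-curve length — a 26-connected chain forced onto
lattice directions can be up to ~8 % longer than the curve it follows —
so the reported length is computed after a 5-point moving-average
smoothing of the path (endpoints pinned); the raw sum is reported
alongside. Radius at a point is the distance-map value there (mm), i.e.
the inscribed-sphere radius; near an end cap or a bifurcation that
sphere is genuinely limited by the cap or the sibling branch, not the
lumen wall, and readings there underestimate the lumen radius. The
curvature estimator resamples the path to uniform 1 mm arc steps and
takes, at each interior sample, the reciprocal circumradius of the
triangle formed with the samples `window` (default 3) steps away;
collinear triples give 0. The estimator is parameter-light and recovers
a 20 mm circle's curvature (0.05 /mm) within 10 %; it is a declared
standard choice, as no canonical discrete-curvature definition exists
for voxel paths.

## Synthetic phantoms

A phantom is a seeded random binary tree of cubic Bezier branches:
exactly n binary bifurcations and n+1 terminal branches, daughters
attached at the parent's endpoint with its end tangent rotated by a
25–40° half-angle about a randomized perpendicular axis. Control points
are jittered perpendicular to the branch direction by the tortuosity
parameter (fraction of branch length; gallery default 0.12 — mildly
tortuous, as peripheral arteries are). Radii taper linearly within a
branch (factor 0.85) and drop to 80 % of the parent's end radius at a
bifurcation, clamped at the gallery minimum. The shipped gallery is ten
phantoms at 1 mm isotropic spacing with radii between 2 and 5 mm and
one to three bifurcations each, extents of 64 mm, branch lengths of
roughly 10–30 mm — sizes chosen so the full ten-phantom sweep runs in
seconds while each vessel still spans tens of voxels in radius-relevant
directions. Rasterization marks a voxel foreground when its center lies
within the local radius of the nearest curve point, evaluated by dense
sampling at ≤ spacing/4 arc steps (error bounded by the sampling step);
sub-voxel radii are clamped to one voxel with a warning. Ground truth
is exact: dense centerline samples (≤ spacing/2 steps), per-sample
radii, and per-branch arc lengths by Gauss–Legendre quadrature.

What the phantoms do *not* emulate: image noise, partial-volume and
contrast effects, segmentation errors, non-circular lumens, stenoses or
aneurysms, and trifurcations. Passing the gallery therefore shows the
geometric pipeline is sound on clean tubular masks; it does not certify
behavior on imperfect clinical segmentations, whose failure modes
(false skeleton branches from segmentation leaks) enter upstream of
this package.

## Evaluation

Centerline accuracy is the directed mean nearest-neighbor distance:
each extracted point is matched to the nearest ground-truth point in
physical coordinates and distances are averaged (a symmetric variant is
available behind a flag). Truth polylines are densified to ≤ 0.25 mm
steps before matching so truth discretization does not inflate the
error. Length accuracy per traced goal compares the measured length
against the analytic arc length of the truth segment between the truth
points nearest to the measured polyline's endpoints — the traced
segment's own truth, since seed and goal snap to centerpoints that sit
about one radius inside the vessel ends. On the gallery the pipeline
achieves per-phantom mean centerline errors of ~0.3–0.5 mm and length
errors under ~2.2 % (computed by `examples/04_evaluate_accuracy.py` and
asserted by the test suite).

## Determinism

Every stage is deterministic: fixed tie-breaks in argmax selections,
fixed face/neighbor scan orders, FIFO BFS, and seeded `default_rng`
streams in the generator. Repeated runs produce bit-identical volumes,
centerlines, maps and geometry reports; the suite asserts this end to
end.

## Known limitations

- Disconnected foreground components require separate seeds; a goal in
  a component not containing the seed fails at the best-path stage.
- Radius readings within one radius of vessel ends or bifurcations
  underestimate the lumen (inscribed-sphere geometry, see above).
- The centerline map is a summary; sub-voxel refinement and spline
  fitting of the output are out of scope.
- Tracking step size equals the local radius, so very short branches
  (shorter than the local radius) may be represented by only their
  endpoints.
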