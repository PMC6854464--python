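# Methods

## Problem and model

A subject rotates 180° at ~0.9 m in front of a fixed RGBD camera. Rigid
per-frame camera poses are assumed given (in a clinical deployment they come
from a prior SLAM stage; here from the fixture generator, optionally
perturbed). What the rigid poses cannot explain is postural sway: breathing
and involuntary body deformation between frames. The pipeline models sway as
a per-frame embedded deformation — a coarse graph of nodes with one 4×3
affine transform each, inducing a smooth warp of nearby space — and
estimates those transforms by nonrigid ICP so that all frames can be fused
into a single consistent torso surface.

The estimator is deliberately geometry-only (no photometric term): the torso
is largely textureless, so the data term is the weighted point-to-point
distance between each transformed node and the exact closest point on the
target surface. Two regularisers make the problem well-posed: a stiffness
term penalising the difference of adjacent nodes' transforms
(as-rigid-as-possible smoothness) and a mobility term parking nodes whose
correspondences were all rejected, which prevents the stiffness term from
flattening unobserved or non-overlapping regions. With correspondences
fixed, the three terms stack into one sparse linear least-squares system
solved in closed form; correspondences are then recomputed from the updated
node positions, and the loop repeats. Transforms are always expressed with
respect to the original node coordinates (absolute, not incremental).

Shortest-distance correspondences are the distinguishing data-association
choice: on a 6 mm graph the nearest *vertex* is up to ~4 mm away from the
true nearest *surface point*, and that quantisation error feeds directly
into the solve. The exact surface hit (vertex, edge or face interior, with
barycentrically interpolated normal) removes it, which is why the
closest-vertex variant is kept only as the comparison baseline.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `graph_voxel` | 6 mm | node density of the deformation graphs |
| `tri_radius` | 2.5 cm | maximum triangle edge in graph meshing |
| `d_max` | 2 cm | correspondence distance gate |
| `angle_max_deg` | 45° | correspondence normal-agreement gate |
| `alpha` | 20 | stiffness weight (single value; no schedule) |
| `beta` | 1 | mobility weight |
| `bundle_size` | 10 | frames pooled per bundle |
| `max_iters` / `conv_tol` | 10 / 1e-4 | per-alignment ICP loop |
| `max_steps` | 100 | global circular refinement steps |
| `global_cycle_tol` | 1e-4 | full-cycle ‖ΔX̃‖_F early stop (None disables) |
| `mls_radius` | 8 mm | MLS smoothing neighbourhood |
| `resample_cell` | 1 mm | fused-model uniform density |
| `poisson_depth` / `poisson_min_samples` | 9 / 10 | implicit meshing resolution / support |
| `m_nearest` | 4 | nodes blended per warp query |
| `fg_margin` | 0.15 m | foreground threshold below the wall median |

The global phase counts one bundle-vs-rest alignment as a step and stops
early when a full cycle moves the bundle transforms by less than
`global_cycle_tol` in Frobenius norm; on converged sequences this saves most
of the step budget without changing the result, and setting it to `None`
restores a fixed 100-step schedule. `m_nearest = 4` follows the common
embedded-deformation practice for human-scale graphs. The foreground margin
assumes the subject stands well in front of the background wall (~0.9 m vs
~2 m), so 0.15 m is conservative on both sides.

## Numerical choices

* The per-triangle closest point is classified into the triangle's
  vertex/edge/face Voronoi regions (exact, no iteration); the point-to-mesh
  query upper-bounds the distance from a few nearest triangle centroids and
  then exactly tests every triangle whose centroid ball can beat that bound,
  so the spatially indexed result equals the exhaustive minimum. Equidistant
  hits break to the lowest face index. A handful of oversized triangles
  (e.g. cap fans of closed fixtures) are tested unconditionally rather than
  inflating the search radius for every query.
* Cylindrical graph parameterisation centres the unwrap angle on a Kasa
  circle fit of the node cross-section; using the patch centroid instead
  folds the angle for wide (near-frontal) views and corrupts the
  triangulation. Near-planar patches fall back to a tangent-plane Delaunay.
* The normal equations AᵀA share one sparsity pattern across ICP iterations
  (the stiffness block is constant; data/mobility are block-diagonal), so
  one LU factorisation serves as a preconditioner for conjugate-gradient
  solves in later iterations, with automatic refactorisation if CG stalls.
  Solutions satisfy ‖Aᵀ(AX−B)‖_∞ < 1e-8·‖AᵀB‖_∞.
* The warp is evaluated as v + Σ w_j[(R̄_j−I)(v−g_j)+t̄_j]; since weights sum
  to one this equals the textbook blended form but is bit-exact under an
  identity field. Degenerate weight sets (all M neighbours equidistant, so
  all raw weights vanish) fall back to uniform weights.
* At zero stiffness the per-node affine is not identifiable from
  point-to-point rows alone (one row per node, four unknowns per
  coordinate); exact affine recovery from perfect correspondences is
  therefore exercised in the vanishing-stiffness limit, where any positive
  stiffness selects the zero-residual constant-affine solution.
* Implicit meshing evaluates a signed moving-least-squares distance (the
  weighted mean of point-to-tangent-plane distances over the
  `poisson_min_samples` nearest oriented points) on a uniform grid of
  2^depth cells along the longest axis, capped at 256 per axis, with a
  coarse pass restricting exact evaluation to a narrow band around the zero
  crossing; marching cubes extracts the surface and the largest component is
  kept. Excess surface farther than 5 mm from the data is clipped after the
  watertightness audit.
* Sequential shortest-arc hue averaging is order-dependent; neighbours are
  taken in ascending point-index order for determinism, which slightly
  biases the mean toward earlier points in pathological hue distributions.

## Synthetic fixtures

The generator emulates the clinical capture at desk scale: a parametric
torso (elliptic-cylinder trunk, two spherical-cap breast bumps, navel
dimple, ~20k vertices) with a smooth skin texture carrying twelve salient
colour spots whose surface positions are known exactly; a camera arc of 30
frames sweeping 180° at 0.9 m with a 320×240 depth sensor; additive Gaussian
depth noise (σ = 2 mm) quantised to 1 mm; a background wall at 2 m; a
2.5 cm depth→RGB baseline; and rigid-pose perturbation (≤ 0.5°, ≤ 3 mm)
emulating upstream SLAM error. Sway is a C¹ time warp that is the identity
at t = 0: a 0.25 Hz breathing displacement of 5 mm along the chest-region
normals plus a 0.08 Hz global lean of 5 mm amplitude at the torso top, with
1.2 s between frames. Landmark annotations are visibility-tested integer-
pixel projections of the spot centres, which adds a realistic ~1 px
(≈ 3 mm at this range) manual-picking quantisation to the landmark metric.

What the fixtures do not emulate: structured-light speckle and edge noise
beyond Gaussian-plus-quantisation, cloth and hair, self-occlusion by arms,
specular skin, and photometric miscalibration. Passing the synthetic suite
therefore demonstrates the estimator's correctness and its behaviour under
the modelled noise, not robustness to every clinical artefact. One property
deserves emphasis: a near-isometric, largely tangential deformation (the
lean) is almost invisible to a geometry-only ICP — surfaces coincide while
material points slide — so the landmark metric improves mainly through the
normal (shape-changing) component of the sway and the recovery of the pose
perturbation. The same limitation applies to the original method on real
torsos.

Problem sizes used by the test-suite and the acceptance script — 30 frames
at 320×240 (≈ 4k graph nodes per frame, three bundles) for the sway-recovery
study, and 8–10-frame arcs for smoke and invariance checks — were chosen so
the whole pipeline exercises every phase, bundle pooling included, at
desk-scale runtimes.

## Volumetry details

Contour corners derive from five torso landmarks (sternum, both inframammary
folds, both anterior-axillary points): per side, the sternum and axillary
positions are copied to the axillary height (top edge) and fold height
(bottom edge) along the torso's up axis and snapped to the nearest mesh
vertices — an interpretation of the rectangular region-of-interest
convention, flagged as such in the code. Contours are Dijkstra geodesics on
the mesh edge graph. Both the segmented breast and the Coons patch are
fan-closed to the same mutual apex (loop centroid displaced along the
negative mean boundary normal by the bounding-box diagonal), so the absolute
difference of their signed divergence-theorem volumes is the enclosed breast
volume. Repeatability (CR = 2.77 σ_w, CV = 100 σ_w / mean) is computed from
paired sessions that differ in posture state and landmark picks.

## Known limitations

* Tangential components of sway are unobservable to the geometry-only cost;
  landmark spread retains that floor.
* The global phase aligns bundle unions, which overlap only near their
  angular seams; very small overlaps would leave the mobility term in
  charge of most nodes.
* The implicit mesher is a uniform-grid MLS field, not an octree screened-
  Poisson solve; at equal `depth` it resolves less fine detail near the
  grid cap, though at torso scale the 1–2 mm cells are below the sensor
  noise.
* Breast segmentation assumes the contour loop cleanly separates breast
  from torso on the mesh; pathological geodesics (e.g. contours pinching
  through the bump) are not auto-repaired.
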