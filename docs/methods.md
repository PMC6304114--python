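# Methods

This note documents the models, algorithms and numerical choices behind
`cavishape`, in the order the pipeline runs them, and states what the
synthetic test bed does and does not establish about real data.

## Geometry and units

Vertices are stored in millimetres; volumes, areas and surface-to-volume
ratios are reported in cm³, cm² and cm⁻¹. The SVR is unit-dependent by
definition, so the centimetre convention is part of the measure. Enclosed
volume is the divergence-theorem sum of signed tetrahedra against the
origin, valid for any closed, consistently oriented triangulation; winding
is repaired on load (breadth-first propagation over face adjacency, then a
global flip if the signed volume is negative). STL input merges vertices by
exact bitwise coordinate equality — STL repeats each vertex per facet, and
exact merge reverses exactly that duplication without welding distinct
vertices; PLY/OBJ indexing is kept as given. Non-manifold edges (more than
two incident faces) are rejected up front with the offending edge named,
because every later stage assumes an edge-manifold surface.

## Preprocessing

`fill_holes` fills background cavities not connected to the volume border
and keeps the largest foreground component, using 26-connectivity for
foreground and 6-connectivity for background — the standard complementary
pairing that avoids topological paradoxes. Marching cubes runs at iso 0.5 on
the binarized mask in physical coordinates; the mask is padded by one
background layer so objects touching the array border still close. An
isolated voxel therefore becomes the edge-midpoint octahedron (volume 1/6 of
the voxel), which is the correct marching-cubes limit, not an error.

Taubin smoothing alternates an inflating λ-step and a deflating μ-step of
the uniform-Laplacian umbrella operator. Defaults λ = 0.5, μ = −0.53,
20 passes: deliberately mild, because the shape variation later measured on
model instances should not be contaminated by shrinkage of the training
surfaces; on a voxelized ball of ~5000 vertices, 50 passes change the
enclosed volume by under 1%, where 50 plain Laplacian passes shrink it by
more than 5%. Boundary vertices are pinned, so boundary loops and the Euler
characteristic are invariant.

Hole cutting removes all triangles touching the geodesic disc (edge-graph
Dijkstra distance) of a configurable radius around the mesh vertex nearest
each seed point; radius 0 removes just the closed fan of the nearest vertex.
The crop plane and the two seed points are user inputs: they encode
anatomical judgements (the floor of the inferior turbinates, the nostril
positions) that cannot be automated here. The result must have exactly two
boundary loops and stay connected, else the operation fails loudly.

## Cylindrical parametrization

The chart is initialized harmonically: *v* solves the cotangent-Laplace
equation with Dirichlet values 0 and 1 on the two boundary loops; *u* solves
it on the mesh cut open along a shortest boundary-to-boundary edge path,
with a unit jump across the cut, giving a periodic angular coordinate. If
the cotangent solve folds any triangle the solve is retried with uniform
weights and the better initialization kept. The loop containing the smallest
vertex index receives v = 0 and the cut starts at its smallest vertex, so
the chart is deterministic and — because cotangent weights and edge lengths
are rigid invariants — exactly equivariant under rigid motions of the input.

Distortion is the area-weighted L2 stretch: per triangle, the affine map
from the unrolled parameter triangle (C·u, H·v) to 3D has singular values
Γ ≥ γ, and the metric is √(Σ A_T (Γ² + γ²)/2 / Σ A_T) with A_T the 3D
triangle area; Γ² + γ² is computed as the Frobenius norm of the Jacobian, so
no per-triangle SVD is needed. The scales are C = mean boundary-loop length
and H = mean iso-u column arc length, which makes stretch scale-comparable
across subjects; an exact unrolling (right cylinder, flat strip) scores
exactly 1. A configurable number of per-vertex relaxation sweeps
(deterministic order, shrinking step set, flip-rejecting) lowers the stretch
further; the default is 2 sweeps, after which the chart is approximately,
not certifiably, locally optimal — exact local optimality would require
per-vertex convergence iterations that buy little on the smooth surfaces
handled here.

**Uniform sampling and v.** The uniform-surface-sampling guarantee is
realized by normalizing *v* once, inside `parametrize`, to the normalized 3D
arc length along each iso-u column. `sample_surface` then traces, for every
grid column u = i/n_u, the polyline where that iso-line crosses mesh edges
(v is strictly monotone along it for a bijective chart) and places the n_v
grid values of v by linear interpolation. Equal v steps therefore travel
equal distances along every column of a fresh chart, while a later
reparametrization (a correspondence warp) deliberately redistributes the
samples. The alternative — resampling every column uniformly by arc length
at every call — would make monotone v-reparametrizations invisible to the
correspondence optimizer and was rejected for that reason.

## Groupwise correspondence

Correspondence quality is the simplified description length
μ = Σ_{λᵢ≥λc}(1 + log(λᵢ/λc)) + Σ_{λᵢ<λc} λᵢ/λc over the eigenvalues of the
sample landmark covariance (1/(nₛ−1) normalization, computed via the
nₛ × nₛ Gram matrix). λc is the expected noise variance; the default
0.0625 mm² is the variance of a 0.25 mm displacement, matching the finest
voxel sizes the pipeline is meant for, and is configurable. μ is zero only
when every eigenvalue is zero and is strictly increasing in each, so any
landmark sliding that inflates model variance is penalized.

The optimizer is deterministic accept-if-improving coordinate descent, so
the μ trace is monotone non-increasing by construction:

- **Rigid + u-rotation.** For each subject in turn, every whole-column roll
  of its landmark grid (a free permutation) is tried jointly with its own
  optimal rigid pose — Horn's closed-form quaternion solution, determinant
  +1 by construction — against the current mean; the fractional u-shift is
  then refined by golden-section search with re-posing at every probe.
  Searching roll and pose jointly matters: either alone stalls in local
  minima because the pose depends on the column matching and vice versa.
- **Non-rigid.** Per-subject periodic bilinear warps of the (u, v) domain on
  control grids of three increasing resolutions (2×4, 4×8, 8×16).
  Control amplitudes are capped at 0.3 of the control spacing and boundary
  rows carry no v-displacement, which keeps every accepted warp bijective;
  v-monotonicity has a closed-form check (row differences of the control
  displacements bounded below by minus the row spacing) and any candidate
  that would fold chart triangles is rejected before evaluation. Each
  candidate is evaluated with its own re-fitted pose, and after each level a
  rigid/u-shift refresh pass runs, because undoing a reparametrization
  typically frees pose corrections that had been compensating for it.

Mirror augmentation enters after correspondence: mirrored landmark copies
are appended (with a `mirrored` covariate flag) rather than re-optimized as
independent subjects — correspondence of a mirrored shape is the mirrored
correspondence.

## Shape model

Shapes are vectors (x₁…x_n, y₁…y_n, z₁…z_n)ᵀ. Generalized Procrustes
analysis removes translation (centroid to origin) and rotation (quaternion
solution, reflections excluded) but deliberately not scale — size is part of
the biology here. The first reference is training shape 0 (any member
works; the iteration replaces it with the evolving mean), and iteration
stops when the mean moves less than 10⁻⁷ mm RMS. PCA is the thin SVD of the
centred data matrix; modes below 10⁻¹² of the leading variance are dropped.
λᵢ is always a *variance* (mm²) in this package; sweeps and clamps are
expressed in SD units k·√λᵢ, with synthesis clamped to ±3√λᵢ by default and
clamping disable-able for analysis sweeps that use ±2.5 SD.

`ProcrustesAligner` and `PointDistributionModel` follow scikit-learn
estimator conventions (fit/transform/inverse_transform, trailing-underscore
attributes, get_params/set_params) and operate on the (nₛ, 3n) matrix, so
they compose with sklearn pipelines; the mesh-processing stages are plain
functions over `Surface` objects because they are not fit/transform shaped.

## Shape–covariate statistics

Per mode: OLS of bᵢ on age; Shapiro–Wilk on the residuals at α = 0.05 (an
automatable replacement for a visual normal-probability plot); if rejected,
the response is shifted to positivity (−min + 5% of the range, recorded and
inverted for predictions) and Box-Cox transformed with λ fitted by profile
likelihood on [−3, 3]; Cook's distance with the 4/n convention flags
influential points, and when any exist the fit is redone by Huber
M-estimation with the p-value taken from the robust t-statistic at n − 2
degrees of freedom. No multiple-testing correction is applied across modes
by default (each mode is tested at 5%); a Benjamini–Hochberg pass can be
applied by the caller on the returned p-values. Regressions use original
(non-mirrored) subjects only — mirrored copies are not independent
observations. Difference maps zero the non-significant modes exactly and
report the per-landmark Euclidean norm of P·b_diff; predictions through a
Box-Cox fit are inverse-transformed, a convention this package documents
rather than inherits.

## Morphometrics

Regions are axis-aligned boxes over triangle centroids on the mean shape;
labels transfer to any synthesized instance by triangle index, so regions
deform with the shape. Boxed regions are closed by fanning each boundary
loop from its least-squares-plane centroid, with winding matched to the
submesh so the result is a closed oriented cycle (the enclosed volume is
well defined even if a non-planar cap folds). A near-planar loop whose
plane projection self-intersects at macro scale (checked on a simplified
ring, tolerance 2% of the loop diameter) is an error; micro-zigzags from
box cuts through triangle strips are not. The respiratory-region volume is
total minus the three boxed volumes, making four-region additivity an exact
identity; areas count labelled faces only (caps excluded), and the caps on
the total shape are included for watertightness. Variation coefficients use
the sample (n−1) SD over the five sweep values.

## Synthetic test bed

`make_template` sweeps a circle along a circular-arc centerline
(default 24×32 vertices, radius 8 mm, arc length 80 mm, 120° bend — nasal
cavity-like proportions) and caps both ends; cap centres mark the hole
seeds. Planted modes are smooth fields — a Gaussian radial bulge, a lateral
bend, a mirror-antisymmetric left-right shift, optionally isotropic scale —
centred, projected out of the six rigid-motion generators (so Procrustes
cannot absorb them), orthonormalized in R^{3n}. Default study conditions:
46 subjects (a typical clinical cohort for this kind of model), ages uniform
on [20, 80] years, mode SDs (2.0, 1.0, 0.5) in R^{3n} units, the first
mode drifting at 0.05 units/year so age explains roughly a quarter of its
variance. Voxelization is an exact centre-inside parity test (scanline along
z with an irrational sub-voxel grid offset so rays avoid edges), suitable
for round-trip tests against marching cubes.

What the synthetic bed does **not** emulate: CT noise and partial-volume
effects, segmentation-threshold uncertainty, mucosal variation, non-tubular
side structures (sinuses), or anatomically realistic mode shapes. Passing
the recovery tests therefore demonstrates the correctness of the
machinery — charts, MDL descent, Procrustes/PCA algebra, statistics,
morphometric identities — not that a clinical population would be equally
compact or that its modes would be equally recoverable.

## Problem sizes and determinism

Desk-scale defaults are a 20×50 landmark grid (1000 landmarks) and
populations of 4–20 subjects; the production-fidelity grid for dense models
is 100 K landmarks (e.g. 250×400), which changes only run time. The test
suite and the acceptance script use the smaller grids so the whole study
re-runs in minutes on one CPU. There is no hidden randomness: every draw
flows from an explicit integer seed, the optimizers are deterministic, and
re-running any stage with the same inputs reproduces its artifacts
bit-for-bit (the command-line interface records config, seed and versions in
a provenance JSON next to each output).

## Known limitations

- Harmonic initialization with cotangent weights is not guaranteed
  fold-free on very irregular or obtuse-heavy meshes; the uniform-weight
  fallback and the flip counter surface the failure rather than hide it.
- The stretch relaxation is a local descent; charts are low-distortion, not
  certified optima.
- The MDL descent is greedy; monotone improvement is guaranteed, global
  optimality is not (the planted-recovery tests bound how much this matters
  at desk scale).
- Warp amplitude caps trade flexibility for guaranteed bijectivity; a
  correspondence needing v-displacements beyond ~0.16 of the tube length
  (three composed levels) will under-fit.
- Region boxes are axis-aligned on the mean shape; the nasal-valve plane is
  an approximation, as in the morphometric literature it follows.
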