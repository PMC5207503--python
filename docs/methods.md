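# Methods

## The estimation problem

The whole-body surface area (WBSA) of a subject is the 2-D area of the body
skin. We approximate the skin by a triangle mesh, so WBSA reduces to the sum
of per-triangle areas `A = ½|u × v|` (u, v the triangle edge vectors). All
mesh coordinates are in decimeters, so areas are in dm² — the scale on which
adult WBSA is a number near 180.

A single depth camera observes only part of the body: the view body surface
area VBSA(θ, φ), a function of the camera's azimuth θ and elevation φ. The
package's purpose is to measure, with exact ground truth, the relation

    WBSA = c₁(θ, φ) · VBSA(θ, φ) + c₀(θ, φ)   (+ optional measurement terms)

over controlled synthetic populations, and to quantify how camera placement,
sensor noise, dropouts and reconstruction error propagate into WBSA
prediction error.

## Ground-truth VBSA via triangle identifiers

Every triangle carries a stable integer ID. The virtual camera casts exactly
one ray per pixel center and keeps the first (nearest) intersection; the
deduplicated, sorted list of hit IDs defines visibility. VBSA ground truth is
the sum of the *original-mesh* areas over that list, so it is completely
decoupled from sensor noise and from any surface-reconstruction artifacts.

Two error mechanisms bound the fidelity of this estimator, in opposite
directions:

* **Partial-visibility overcount.** A triangle straddling the silhouette is
  counted whole even though only part of it is visible. Overcount shrinks as
  triangles get smaller (subdivision).
* **Sampling undercount.** A triangle is only registered if some pixel-center
  ray hits it. When the mesh density approaches the ray density, small and
  strongly foreshortened triangles (near silhouettes and grazing surfaces)
  fall between rays. For a convex body whose visible triangles receive on
  average `a` pixel samples at normal incidence, the expected un-sampled area
  fraction is roughly `∫₀¹ e^{−a·c} dc = (1 − e^{−a})/a` (c the incidence
  cosine) — about 7% at `a ≈ 14`, under 1% only for `a ≳ 100`.

The sphere benchmark makes this concrete. An icosphere (R = 5 dm) viewed
from D = 43 dm has analytic visible-cap area `2πR²(1 − R/D) = 138.81 dm²`.
At 640×480 (43° vertical FOV) the sphere projects to ~71 px radius
(≈ 17 700 rays): a 320-face icosphere reproduces the cap to −0.07%, a
1280-face one to −2.2%, but a 5120-face one undershoots by −7.7% and a
20480-face one by −21% — finer meshes are *worse* once triangles shrink
below the pixel footprint. At 1280×960 the 5120-face sphere is back to
−1.3%. Practical rule: subdivide only until the overcount is acceptable,
never beyond the resolution's sampling capacity. Bodies rendered at the
default 640×480 from 4.3 m are therefore generated with a few thousand
triangles, not tens of thousands.

Because the same systematic bias applies to every subject at a given camera
pose, the *regression* of WBSA on VBSA absorbs it into c₁ — rank
correlations and fits are far more robust to the sampling regime than the
absolute VBSA values.

## Camera model

Pinhole projection `x = fX/Z, y = fY/Z` through the intrinsic matrix
`K = [[f·sx, f·s_θ, ox], [0, f·sy, oy], [0, 0, 1]]`. Defaults emulate a
Kinect-class sensor: 640×480, 43° vertical field of view, zero skew,
principal point at the image center. The camera sits at
`C = look_at + D·(sinθ cosφ, sinφ, cosθ cosφ)` in a world frame with +y up,
the subject facing +z and the subject's left toward +x; the look-at point
defaults to the body center (half stature). At |φ| = 90° the up reference
degenerates and the subject's facing direction is used to keep the image
oriented. The framing relation `maxStature = 2 tan(ψ) D` (ψ = *half* the
vertical FOV — the only reading under which the geometry closes) gives the
default working distance: D = 43 dm accommodates subjects beyond 2.2 m.

Ray–triangle intersection is a vectorized Möller–Trumbore test with
inclusive edge handling and a deterministic nearest-depth, lowest-ID
tie-break. For speed, each triangle is tested only against the pixels of its
conservative screen-space bounding rectangle; this is exact (a pixel-center
ray can hit a triangle only if it lies over the triangle's projection), and
unit tests verify per-pixel identity with a dense all-pairs
plane-plus-barycentric scan.

### Sensor noise

Depth sensors show axial noise (along the ray) growing roughly quadratically
with distance and sharply near grazing incidence, and lateral noise of
order one pixel. The bundled model perturbs each depth by
`N(0, σ_a(z, α)²)` with `σ_a(z, α) = 0.0012 + 0.0019(z − 0.4)² +
(0.0001/√z)·α²/(π/2 − α)²` (meters; z depth, α incidence angle), taken from
the published Kinect characterization by Nguyen and colleagues, and applies
lateral jitter by re-reading each pixel's depth from a Gaussian-offset
neighbour (sd 0.815 px). Noise corrupts geometry only; the ground-truth
visibility list is untouched. Noise is off by default and fully
configurable.

### Holes

Depth dropouts (IR interference, reflective skin) are emulated by removing
each visible triangle independently with probability p and blanking its
pixels. The expected remaining VBSA is (1 − p) · VBSA_gt; the simulation is
seeded and the package verifies the expectation by Monte Carlo. Spatially
correlated holes are a configuration extension, not implemented.

## Single-view reconstruction

Because the point cloud is *organized* (points live on the pixel grid),
surface reconstruction is direct: every 2×2 pixel quad with four finite
depths and maximum pairwise depth difference below a threshold (default
0.2 dm) emits two triangles; larger jumps mark silhouette boundaries and are
left unbridged. This replaces heavyweight unorganized-cloud pipelines
(normal estimation + greedy triangulation) while exercising the same error
pathway: holes and jagged boundaries perturb the measured area.

The unrecoverable part of a smooth convex surface is the silhouette rim
band, which projects into sub-pixel space (for the benchmark sphere, view
angles 80°–83.3° project into ~0.3 px at 1280×960 yet carry ~6.5% of the
cap area). The reconstructed area therefore converges to the visible area
from below, at a rate ∝ 1/√f.

An optional pre-reconstruction cleanup fits, per pixel, a least-squares
plane `Z = aX + bY + c` to the 3×3 neighbourhood of 3-D points and moves
the pixel's depth along its own ray onto that plane (an exact no-op for
noise-free planar data), then thins points on a cubic voxel grid keeping
the sample nearest each voxel center.

## Synthetic bodies and populations

The humanoid is a deliberate parametric-primitive stand-in, not an
anatomical model: head ellipsoid, torso as a vertically varying elliptic
tube (hips–waist–bust–shoulders control profile, monotone-cubic
interpolated), tapered-tube legs, capsule arms. Design features that matter
for the angle study:

* frontal half-width exceeds sagittal half-depth everywhere on the torso, so
  the frontal view exposes the maximum VBSA;
* arms are bent slightly forward and inward, so the distal arms sit in front
  of the thighs — visible frontally, occluded from behind, creating the
  front/rear asymmetry and the mid-azimuth occlusion regime;
* bounding-box height equals the requested stature exactly (soles at y = 0,
  head top at stature), and all cross-section dimensions scale with
  stature × girth, so WBSA is strictly increasing in both.

Parameters: stature (cm), girth (dimensionless cross-section scale — the
weight proxy), muscle_fat ∈ [0, 1] (low = fat waist and thighs, high = lean
with thicker limbs), gender_shape ∈ [0, 1] (blends shoulder/hip ratio, bust
depth, neck), age (years, used only for group labels). Measurements are
*analytic* cross-section perimeters (exact ellipse perimeters via the
complete elliptic integral) at named heights, plus a weight proxy = body
volume × 1 kg/L. Group labels: male/female at gender_shape 0.5; kid/adult at
age 15; stature small ≤ 140 cm < normal ≤ 200 cm < big (the small cut is
configurable).

Populations:

* **random**: every parameter i.i.d. uniform over configurable ranges
  (defaults: stature 120–220 cm, girth 0.7–1.5, muscle_fat and gender_shape
  0–1, age 5–80). Uniform rather than normal sampling is deliberate — it
  over-represents the extreme bodies that stress a WBSA predictor. Because
  parameters are independent, kids can be tall and adults short; the labels
  are grouping devices, not a demographic model.
* **NHANES-style**: a base table of subjects (fixed stature/age/gender) each
  replicated over a near-square grid of (girth factor, muscle_fat) values —
  fat-to-skinny families of the same individual. Output size is exactly
  |base| × k.

Both generators are pure functions of (config, seed).

What the generator does *not* emulate: real anthropometric covariance
(height–weight correlation), pose variation, soft-tissue deformation,
surface detail (ears, fingers), skin reflectance. Tests passing on these
bodies demonstrate the *pipeline's* correctness and the geometric
angle-dependence mechanisms; absolute error magnitudes on real bodies will
differ.

## Regression and validation

Per camera angle, ordinary least squares (SVD-based `lstsq`, not normal
equations, for conditioning) fits WBSA on VBSA plus optional measurement
columns. Validation is k-fold cross-validation, k = 10, with folds drawn as
a seeded uniform random permutation split into near-equal parts. Errors are
pooled over held-out sets (not fold-averaged): RMSE = √(mean squared error)
in dm², MSPE in dm⁴, MAPE = mean(|err|/truth)·100%. Residual diagnostics
provide standardized residuals, normal theoretical quantiles (Blom plotting
positions) for QQ plots, and a Breusch–Pagan statistic for the
heteroscedasticity that appears at high-occlusion angles, where large bodies
have disproportionately variable occluded area. Spearman correlation (average
ranks on ties) summarises variable association; constant columns are flagged
as undefined rather than zeroed. Groups smaller than the coefficient count
plus two are skipped with a warning.

## Numerical choices and degenerate inputs

* Quad OBJ faces are fan-split at the first vertex: (v0,v1,v2) + (v0,v2,v3);
  face IDs are assigned in file order and survive round-trips.
* Subdivision is flat midpoint 1→4 (no smoothing) so total area is conserved
  to accumulation tolerance; children record their parent's ID.
* Degenerate (collinear) triangles have area 0; meshes with repeated vertex
  indices in a face are rejected.
* Depth maps use NaN as the miss sentinel (written explicitly by the text
  writers); hit-ID maps use −1.
* Equal-depth ray hits resolve to the lowest face ID, making every cast
  bit-reproducible.
* The camera must see the whole mesh in front of the image plane; a camera
  inside the mesh bounding sphere raises rather than returning nonsense.
* Cross-validation with k > n, empty parameter ranges, non-positive
  framing inputs, and rank-deficient designs (reported with the offending
  column names) all raise.

## Problem sizes used in the bundled studies

The bundled tests and the acceptance script run populations of 100–200
subjects, mini-sweeps over 2–5 azimuths at 320×240, and frontal casts of 200
bodies at 640×480 — sizes chosen so the full suite re-runs in well under a
minute per study while leaving every statistical conclusion (rank
correlations, slope ordering, noise-floor recovery) unchanged at larger n.
The full 65-cell angle grid at 640×480 over thousands of subjects is
available through `vbsalab sweep` and scales linearly.

## Known limitations

* ID-harvested VBSA is biased low when triangle density exceeds ray density
  (quantified above); choose subdivision to match resolution.
* The humanoid's buried surfaces (component overlaps at joints) contribute
  to WBSA but can never be visible, slightly inflating WBSA relative to a
  watertight skin; this acts as a constant factor absorbed by the fits.
* Hole simulation is i.i.d. per triangle; real dropouts are spatially
  correlated.
* The Du Bois comparison depends on the volume-based weight proxy; it is a
  consistency reference, not a calibration.
* No lens distortion, RGB shading, or IR reflectance simulation.
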