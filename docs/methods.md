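# Methods

`thermocloud` turns a moving 2D LiDAR line scanner and a radiometric thermal
camera into a single instrument that measures surface temperature in 3D, and
segments per-apple fruit surface temperature (FST) from orchard-row scans.
This note documents the models, the parameter choices that matter, what the
synthetic scenes do and do not emulate, and the numerical decisions a
maintainer would want written down.

## Sensor model and frames

The scanner produces 180° profiles on a uniform angular grid (default
0.1667°) at 25 Hz while the platform travels at 20 mm s⁻¹ perpendicular to
the scan plane; profile *k* is therefore offset by `k·v/f` = 0.8 mm along the
travel axis. The assembled cloud lives in the rig frame: scan plane x–z
(`x = r cos θ`, `z = r sin θ`), travel along +y, units metres throughout.
Unit conversion (the board geometry is specified in mm) happens only at
configuration boundaries.

Images are 640 × 480 radiometric grids already in °C; no rescaling is applied
on read. Pixel origin is top-left, x rightward, y downward, with pixel
centres at integer coordinates.

A `RigidTransform` (R, t) maps points as `p → R p + t`; the camera-from-LiDAR
extrinsics, the board poses, and the ICP corrections are all instances of it.

## Intrinsic calibration

Chessboard corners are invisible to a thermal camera, so the target is a
0.5 × 0.6 m board with 30 heated bulbs on a 5 × 6 grid at 100 mm pitch. The
projection model is the standard pinhole with radial/tangential distortion:

```
x_d = x (1 + k1 r² + k2 r⁴ + k3 r⁶) + 2 p1 x y + p2 (r² + 2x²)
y_d = y (1 + k1 r² + k2 r⁴ + k3 r⁶) + p1 (r² + 2y²) + 2 p2 x y
u = fx·x_d + cx,  v = fy·y_d + cy           (r² = x² + y² on normalised coords)
```

No thin-prism terms; homogeneous normalisation by Z precedes distortion.

**Staged blob detection.** The image is scaled to a temperature range
(initially its own [min, max]) and quantised to 8 bit with half-up rounding
(deterministic across platforms). Detection is a multi-threshold sweep:
binarise at `minThreshold … maxThreshold` in `thresholdStep` increments,
keep bright 8-connected components with area inside `[minArea, maxArea]`,
and merge component centres within 10 px across slices into one blob (mean
centre, mean equivalent radius). Bulbs are *bright* blobs — polarity is
fixed hot. Three sensitivity presets are tried in order; preset 1 is
(20, 220, 15, 160, 230); presets 2–3 are package defaults that widen the
sweep and loosen the area gate, and are fully configurable. Success means
*exactly* 30 blobs in a valid grid arrangement; otherwise the lower bound of
the range rises by 5 °C (the upper bound is never lowered) and the cycle
repeats, for at most 4 ranges × 3 presets = 12 attempts before the image is
discarded. Discards are recorded, never silently dropped.

**Grid ordering.** Blob centres are projected onto the two principal axes of
the constellation, which coincide with the grid axes of a regular pattern
under any in-plane rotation; the axis admitting a clean partition into
`rows` groups of `cols` (split at the largest gaps) is the row axis, with
signs fixed against the image axes — unambiguous up to ±30° in-plane
rotation. Under strong perspective keystone the gap partition can fail;
a fallback then fits a homography on the four extreme corner blobs (maximum-
area hull quadrilateral) and snaps every centre to integer grid indices,
accepting the assignment only if it is a bijection with residuals < 0.3 grid
units and the right orientation.

**Estimation.** Zhang's closed-form solution from per-view plane
homographies initialises the camera matrix (distortion at zero), per-view
poses come from the homographies, and a joint nonlinear refinement
(`scipy.optimize.least_squares`, trf) minimises the total squared
reprojection error over (fx, fy, cx, cy, k1, k2, k3, p1, p2) and all view
poses. Per-view and global RMSE are reported in pixels. At least three
views with distinct orientations are required; a rank-deficient constraint
system (e.g. identical poses) raises a degenerate-views error.

## Extrinsic calibration

Per scan of the board:

1. **Crop** an axis-aligned box so the board is the largest remaining plane.
2. **RANSAC plane** — 1000 iterations, 10 mm distance threshold, minimum
   500 inliers (board at 1–2 m, ±5 mm range noise), refined by a total-
   least-squares fit on the consensus set. The inliers' oriented in-plane
   extents must match the board within ±10 %; a board cut off by the scan
   boundary fails here and the scan is discarded.
3. **PCA initial pose** on the 10 mm voxel-downsampled inliers: largest
   eigenvalue → board long axis, smallest → normal, centroid → origin.
   Signs are a convention the optimiser cannot recover: the normal faces
   the sensor origin, the long axis has positive dot with the up vector,
   and the short axis completes a right-handed frame.
4. **ICP refinement** of a synthetically sampled board model (5 mm grid,
   ≥2 data points per model cell at the 10 mm voxel size) onto the inliers.
   The composition convention is `T_final = T_initial ∘ T_corr` with
   `T_corr` acting in the board frame; a directed test pins it. The RMS
   correspondence distance is non-increasing and is used for convergence;
   non-convergence returns the last iterate with a flag.
5. **Bulb positions**: the 30 grid points mapped through `T_final`, in the
   same canonical row-major order the image sorting produces. With the
   right-handed board frame (X along width, Y up, Z toward the sensors) the
   image order and the board order correspond without mirroring.
6. **Pose solve** from the ≥6 pixel/3D pairs: pixels are undistorted by
   fixed-point iteration; a plane-homography pose (the board is coplanar)
   or an 11-parameter DLT (general case) initialises; Levenberg–Marquardt
   refines the full distorted-model reprojection error.

Each valid scan yields a candidate (R, t). Every candidate, plus the
element-wise mean of all candidates (rotation matrices averaged and
re-projected onto SO(3)), is scored by the cross-scan reprojection RMSE

```
rmse = sqrt( Σᵢ Σⱼ ‖m'ᵢⱼ − mᵢⱼ‖² / (N·M) )
```

over all N valid scans × M features, and the minimum is selected. Both the
per-candidate table and the mean candidate's score are reported.

*Known sensitivity:* a single fronto-parallel planar target constrains the
tilt/lateral-translation combination weakly, so individual per-scan
candidates can be off by 10–20 mm at 0.2 px feature noise even though their
reprojection residuals are small. Board placements covering the camera
frame at varied tilts decorrelate these errors; the selection (typically
the mean candidate) then lands within a few mm / ≤0.3° on the synthetic
rig. The placement sampler rejects poses whose bulbs leave the image,
mirroring how the pattern is positioned in practice.

## Fusion

Every LiDAR point is mapped to the camera frame, projected with the full
distortion model, and assigned the *nearest* pixel's temperature
(interpolation would blur blob/background and leaf/fruit boundaries).
Points projecting outside the image — or behind the camera, a case the
in/out rule alone does not cover — receive the sentinel, default −10 °C,
which must lie outside the declared scene temperature range. No point is
ever dropped; fusion is idempotent. There is no occlusion reasoning: a
point hidden behind foliage samples the foreground pixel, exactly as a
single-view method must. An optional z-buffer flag exists but defaults off
to stay faithful to that behaviour.

## Orchard pipeline

**Side alignment.** Opposing row scans are registered by ICP from a
platform-geometry initial guess. The sides genuinely share only thin
structures (trunks, the orchard floor, canopy seams), so correspondences
are trimmed — coarse-to-fine at 50/25/10 mm — which lets the shared
structures dominate the final iterations. The merged cloud keeps duplicate
overlap points (FST averaging is robust to them) and per-point side
provenance.

**Stems and trees.** A bivariate histogram (50 mm bins) of the 0.2–0.8 m
trunk band over the ground plane; local maxima above the median non-zero
count, non-maximum-suppressed at 0.5 m (half the 0.95 m tree pitch), are
stem positions. Each tree is a 0.45 m cylinder around its stem — less than
half the pitch, so neighbouring trees never share points.

**Curvature.** For each point, the k = 30 nearest neighbours (plus the
point) are mean-centred; the covariance eigenvalues λ1 ≥ λ2 ≥ λ3 give the
change-of-curvature `c = λ3/(λ1+λ2+λ3)`, high on locally spherical
surfaces. k = 30 matches the fruit-surface patch size at the scanner's
point spacing and is exposed in the API. Per cloud, c is affinely rescaled
so min → 0 and max → 100; the bounds are attained on every non-constant
cloud. Degenerate (duplicate-point) neighbourhoods get curvature 0 and a
flag.

**Thresholds.** Apples are the high-curvature, high-reflectance class:
candidates satisfy `C_th ≤ C` and `R_th ≤ R`. Thresholds come from the
feature distributions only (no labels): a Gaussian-KDE valley between the
two dominant modes where the density is genuinely bimodal — the valley is
accepted only if it dips below 0.7 × the weaker mode, which reflectance
(apple ≈ 0.85 vs foliage ≈ 0.55 at 905 nm) always satisfies — otherwise a
percentile fallback, default the median, keeps the upper half and leaves
the discrimination to the joint criterion. Both the method used and the
values are recorded. A percentile-only mode is also available; neither
variant is claimed to be the original instrument's exact procedure, which
is not documented beyond "probability density function".

**Fruits.** Candidates are clustered by single-linkage Euclidean clustering
(connected components of the 20 mm ε-graph); clusters under 30 points are
dropped. Per cluster: centroid, algebraic least-squares sphere radius, and
FST statistics (mean/min/max/SD) over non-sentinel temperatures only.
East/west labels follow the sign of the centroid's offset along the
configured cross-row normal; an exact zero ties deterministically to east.

## Synthetic scenes

The simulator exists so every stage is testable against ground truth
without hardware; its defaults are the reference rig's printed
specifications (LiDAR 0.1667°/180°/25 Hz, platform 20 mm s⁻¹, camera
640 × 480 at 0.2 m above the scanner). Default range noise is σ = 5 mm,
thermal noise σ = 0.05 °C (the camera's stated thermal resolution class).
Same seed ⇒ bit-identical output.

*Calibration board and metal tree* are ray-cast against analytic
rectangle/sphere/cylinder primitives (closed-form intersections, verified
against independent formulas to 1e-9). The thermal frame renders the board
at 21.4 °C over a 15 °C background with Gaussian bulb spots peaking at
46.3 °C (σ = 6 px, sized so preset 1's area gate accepts the threshold
slices) — the fused-cloud statistics of the reference rig. The metal tree
carries 12 × 80 mm and 3 × 60 mm spheres, white (high-reflectance) and
black (low) coated, on five bars at 0.30 m spacing.

*Orchard row* (default 5 trees at 0.95 m pitch, 10 fruits/tree) is sampled
directly on organ surfaces rather than ray-cast: the fruit pipeline
consumes already-fused thermal clouds with per-point organ labels, for
which occlusion realism adds nothing while multiplying run time. Sampling
densities follow one scanner-resolution story (≈40–65 k points/m²:
500/fruit, 200/leaf) so that k = 30 neighbourhoods stay within a single
surface — the property the curvature feature relies on. Trunks are
vertical cylinders, leaves oriented disks, fruits spheres with
reflectance 0.85 ± 0.02 vs foliage 0.55 ± 0.05 and a smooth surface
temperature field: per-fruit base 18.3 °C (±0.3 between fruits), +0.5 °C on
the east half of each tree, ±0.3 °C within a fruit along the sun direction,
plus σ = 0.1 °C fusion noise per point; organ temperatures for leaves
(17.5 ± 0.6 °C) and trunks (20.6 ± 0.65 °C) bracket the fruit range as in
late-season field conditions. Points above the camera's vertical field of
view carry the −10 °C sentinel. Each point is assigned to the scan side
its surface normal faces; the ground strip and the ~6 cm trunks are thin
structures visible from both sides and anchor the side-to-side ICP. The
west cloud is expressed in the west scanner's frame (180° about the
vertical plus an offset), with the true inter-side transform in the truth
record.

What the generator does **not** emulate: emissivity and atmospheric
effects, wind motion, occlusion inside the canopy (and hence the
foreground-sampling error real single-view fusion suffers), leaf meshes
beyond flat disks, registration drift from GNSS/IMU noise, and natural
fruit clustering in touching pairs. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms under the
stated noise models — not field-condition accuracy.

## Metrics

MBE = mean(predicted − observed); RMSE on the same differences; R² from the
least-squares line and `R²_adj = 1 − (1−R²)(n−1)/(n−p−1)`. Detection F1
uses greedy closest-first one-to-one matching within a radius; greedy
equals optimal matching when targets are separated by more than twice the
radius, the regime fruit centroids occupy. Sphere reports extract each
sphere's points within radius + 10 mm of its centre, flag empty spheres,
and regress per-material means against the manual references. With a
constant reference the fit is degenerate; the report calls it perfect only
when predictions match to numerical precision.

## Numerical choices and degenerate inputs

- Half-up rounding for 8-bit scaling and nearest-pixel lookup; ties cannot
  depend on platform banker's rounding.
- Rotations are re-orthonormalised through SVD at construction; matrix
  means are projected back to SO(3).
- PLY coordinates are stored as doubles, attributes as 32-bit floats
  (temperature explicitly so); the sentinel is written verbatim.
- RANSAC uses a seedable generator; all simulation randomness flows from a
  single `numpy` Generator per scene.
- Empty crops warn rather than fail; empty fruit lists are valid output;
  ICP non-convergence returns the last iterate flagged.

## Problem sizes

Default test/verification scales: 0.8 m traverses (~1000 profiles × 1081
beams) for calibration scenes, 10 board placements for the extrinsic
experiment, 20 analytic views for intrinsics, and the 5-tree orchard
(~215 k merged points). These sizes keep every experiment deterministic
and fast while leaving each estimator comfortably over-determined.

## Known limitations

- Per-scan extrinsic candidates inherit the planar-target pose ambiguity
  described above; the cross-scan selection mitigates but cannot bound it
  for a single scan.
- Reflectance is used raw; no range/incidence normalisation is applied, so
  the thresholds assume reflectance contrasts survive the sensor's own
  processing.
- The stem histogram assumes a row-aligned frame with a known up axis and
  trunks visible in the 0.2–0.8 m band.
- Sphere extraction by geometric distance assumes the evaluation frame's
  geometry is known exactly; field use would first register the frame.
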