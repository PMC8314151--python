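# Methods

## The metric

Let M₁, M₂ ⊂ ℝ³ be two binary masks on a shared voxel grid with spacing
(d₁, d₂, d₃) mm, S₁, S₂ their surfaces and |Sᵢ| the surface areas. The
border region of surface Sᵢ at tolerance τ, B_{i,τ}, is the set of points
within Euclidean distance τ of Sᵢ. The surface DSC at tolerance τ is

    ( |S₁ ∩ B₂,τ| + |S₂ ∩ B₁,τ| ) / ( |S₁| + |S₂| ),

the area fraction of the combined surface for which the two delineations
agree to within τ. It is symmetric, lies in [0, 1], is nondecreasing in τ,
and reaches 1 for any two nonempty masks once τ exceeds the grid's physical
diagonal. The volumetric DSC 2|M₁∩M₂|/(|M₁|+|M₂|) and its sparse-label
aggregate 2·Σ_p|M₁,p∩M₂,p∩L_p| / Σ_p(|M₁,p∩L_p|+|M₂,p∩L_p|) (L_p = labeled
region of patient p; predictions are masked by L_p, so unlabeled voxels are
neither penalised nor rewarded) are provided for comparison.

## Surface representation

Counting surface voxels approximates a surface integral poorly, especially
on anisotropic CT grids. Surface points are instead placed on a raster
shifted by half the voxel spacing on each axis, so that every raster point
is surrounded by exactly 8 voxels. For a binary mask there are 2⁸ = 256
possible neighbor constellations; each is triangulated once with marching
cubes (scikit-image's Lewiner case table; vertices at exact edge midpoints,
the only consistent choice for binary data at isolevel ½) and the triangle
area in mm² is stored in a look-up table. A mask is converted to a surface
image by one vectorised table lookup over its constellation codes, with
out-of-volume voxels treated as background so every component's surface is
closed. The whole pipeline is O(N) in the voxel count.

Conventions fixed here (the underlying constellation geometry does not
determine them):

- Raster point (i, j, k) of the (n₁+1, n₂+1, n₃+1) surface raster sits at
  world position ((i−½)d₁, (j−½)d₂, (k−½)d₃) and neighbors voxels
  (i−1..i, j−1..j, k−1..k).
- Ambiguous (diagonal) constellations are resolved by the Lewiner case
  table; the resulting 256 areas are frozen by a checksum test, so any
  drift in the dependency is caught rather than silently absorbed.
  Per-constellation areas for ambiguous cases can legitimately differ
  between marching-cubes variants; this slightly affects area estimates but
  not the metric's structure.

## Distances and tolerance rounding

Border-region membership is evaluated with an exact Euclidean distance
transform (scipy's EDT with anisotropic sampling in mm) of each surface
image; sources are exactly the raster points with positive area. Chamfer
approximations are avoided because their error would leak into the
acceptance band. Distances between raster points form a discrete set
D = {√((i·d₁)² + (j·d₂)² + (k·d₃)²)}; the requested tolerance is rounded to
the nearest element of D before thresholding (ties resolve to the smaller
element — conservative and deterministic). A relative slack of 1e−9 absorbs
floating-point differences between the transform and the rounded tolerance.

Degenerate inputs: two empty masks give 0/0 and return an explicit
undefined flag (NaN) rather than a default score; exactly one empty mask
scores 0. Cohort summaries exclude undefined values and count them
separately.

## Tolerance calibration

The per-organ tolerance is meant to equal typical expert disagreement: for
every pair of observers on every calibration scan, the bidirectional
surface distances are sampled — for each surface element of one contour,
its distance to the other contour's surface, weighted by the element's area
— pooled per organ, and summarised by an area-weighted percentile (default
95th, configurable). The weighted percentile uses the cumulative-area
"lower" convention at exact boundaries, making the statistic deterministic.
Pooling across scans before taking the percentile (rather than averaging
per-scan percentiles) is a design choice: it weights every surface element
equally regardless of scan, and is validated by parameter recovery (slab
pairs offset by δ ∈ {1, 2, 3} mm calibrate to within ±0.25 mm of δ).
Calibration and evaluation cohorts must be disjoint.

## Cohort summaries

Per organ: median, quartiles by linear interpolation between order
statistics ("type 7" — a frozen, documented choice; the convention is not
determined by the statistics themselves), whiskers at the most extreme
values within 1.5·IQR of the quartiles, values beyond as outliers, and a
notch of ±1.57·IQR/√n around the median (the standard notched-box 95% CI).
Paired comparisons (e.g. model vs reference against human observer vs
reference) are matched by (case id, organ); unpaired records are excluded
from difference statistics and tallied. Mean paired differences are
reported in percentage points and classified against a ±5 pp band of
non-substantial difference.

## Synthetic phantoms

All test inputs are generated: digitized spheres (voxel center strictly
inside the radius), cuboids, full-cross-section slabs, arrangements of
congruent disjoint cubes, sparse slice labelings and seeded perturbations.
Default geometry is a 64³ grid at 1 mm isotropic spacing, with an
anisotropic variant at (0.976, 0.976, 2.5) mm matching standard
head-and-neck planning-CT voxels. The phantoms provide exact expectations —
counts, component separations, the (n−k)/n score of a k-of-n displaced-cube
pair — so the metric code can be checked against closed forms and
brute-force oracles (O(n²) nearest-point distances; a single full-volume
triangulation for areas). They do not emulate anatomy, CT intensities,
imaging noise or observer behaviour, so passing tests demonstrate
correctness of the metric computation, not clinical performance of any
segmentation model.

Problem sizes in the test suite and benchmark script (small random masks up
to 16³ for oracle equivalence, 18³ pairs for invariant sweeps, 64³–70³ for
the headline phantoms and runtime scaling) were chosen so the full suite
completes in well under a minute on one CPU while still exercising every
code path at realistic organ scale.

## Known limitations

- No resampling or registration: masks must share shape and spacing, and
  mismatches are errors by design.
- Distances are measured between surface raster points, not point-to-
  triangle; this matches the tabulated-surface formulation but differs from
  mesh-based distance at sub-voxel scale.
- Probabilistic (fractional) masks, Hausdorff/average-surface-distance
  metrics, DICOM-RT structure sets and mesh export are out of scope.
- Inter-observer calibration models only between-observer variability, not
  intra-observer repeatability or consensus (e.g. STAPLE) estimation.
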