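# Methods

## The measurement model

The quantity of interest is the signed bilateral ulnar length difference
Δ = L_right − L_left of one patient, measured on triangulated surface
models of both ulnae. The procedure standardises *where* length is read
off by construction of a per-patient measurement axis:

1. The left ulna is reflected across a plane (the y–z plane through its
   centroid by default; the choice is immaterial because the subsequent
   rigid registration absorbs the composition of any two reflections).
   Face winding is reversed so outward orientation is preserved.
2. A rigid initialization maps the moving bone's centroid onto the fixed
   bone's centroid and its proximal→distal landmark direction onto the
   fixed one. Enforcing proximal-to-distal correspondence through the
   landmarks excludes the 180°-flipped local minimum that plain
   moment-based initializations are prone to with elongated bones. Roll
   about the length axis is fixed using the bow direction (the vertex
   farthest from the landmark chord), which is rigid-covariant.
3. ICP refinement: each iteration pairs moving vertices with their
   closest points on the fixed *surface* (exact point-to-triangle
   distances, KD-tree prefilter over triangle centroids) and solves the
   least-squares rigid update by SVD (Kabsch). The per-iteration RMS is
   non-increasing; iteration stops when the improvement falls below
   `tol` (default 1e-4 mm) or at `max_iter` (default 100; then the
   result is returned flagged unconverged rather than raised).
4. Alignment gate: olecranon tips within `olecranon_tol` (2 mm) and dome
   tips within `dome_lateral_tol` (2 mm) *perpendicular* to the axis.
   The along-axis dome separation is the measurand and is never
   penalised. These tolerances are a design decision of this package —
   they quantify "the olecranons overlap and the domes are aligned" well
   below anatomical scale — and every run logs the values used.
5. The longer ulna (larger olecranon-tip-to-dome-tip chord; ties resolve
   to the first argument) is cut by a plane through the chord midpoint
   with normal along the chord. A least-squares circle (algebraic Kasa
   fit refined geometrically with Levenberg–Marquardt) is fit to the cut
   contour after projection into the plane; open contours (non-watertight
   meshes) are fit the same way. The axis runs from the fitted center to
   the dome tip.
6. Δ is the difference of the two dome-tip projections on the axis,
   reported right-minus-left. The relative difference divides |Δ| by the
   projected olecranon-to-dome length of the *longer* ulna — the longer
   bone defines the axis, so its length is the only one already measured
   on that axis.

### Why ICP is anchored proximally

For two bones that differ genuinely in length, the shaft is nearly
translation-invariant along its own axis, so whole-surface ICP
equilibrates by splitting the end mismatch between the olecranon and the
dome — biasing the measured dome-height difference towards Δ/2. The
clinical procedure aligns the bones *from proximal to distal* and accepts
a match when the olecranons overlap; `measure_pair` therefore restricts
ICP correspondences to the proximal half of the moving bone (vertices
with chord coordinate ≤ `proximal_fraction` = 0.5, computed from the
moving bone's own landmarks and hence invariant under rigid motion of the
inputs). `icp_register` itself defaults to whole-surface correspondences;
the mask is an explicit argument. An optional `trim_fraction` drops the
worst correspondences per iteration for noisy surfaces (default off).

### Landmarks

The olecranon and dome tips are detected as the extremal surface points
along the first principal axis of the vertex cloud, each refined to the
point farthest from the centroid within its end cap (outer 15% of the
axial extent). The ends are disambiguated by end-cap girth — the
olecranon end is the wider one — and the caller can override the
assignment or supply landmarks outright (manual picks or ground truth),
which keeps the geometric stages testable in isolation. Meshes whose
longest principal extent is less than 3× the next are rejected as
non-elongated.

## Cohort statistics

- **Adjudication**: observer discrepancy ≤ 1 mm → final value is the
  two-observer mean; > 1 mm → a third observer's value is required and
  used, and the case is flagged. (An unresolved flagged case is an
  error naming the patient.) The threshold is exactly 1 mm exclusive:
  a discrepancy of 1.0 mm is averaged, not adjudicated.
- **Summary**: means and SDs (n−1 denominator) of signed, absolute and
  relative differences; min/max of absolute differences.
- **Subgroup tests**: two-sample t-tests of absolute and relative
  differences across age group (18–49 vs 50+), sex, and malunion side.
  Welch's unequal-variance test is the default; Student's pooled test is
  available by flag, since published reports rarely state the variant.
  Subgroups with fewer than 2 members in a level are omitted rather than
  tested. Zero-variance degeneracies return t=0, p=1 (equal means) or
  p=0 (separated means).
- **Normality**: one-sample Kolmogorov–Smirnov against a normal with
  estimated mean/SD. Because the parameters are estimated from the
  sample, the Lilliefors correction is applied by default (the naive KS
  p-value is anticonservative); `method="naive"` restores the plain test.
  Constant samples are reported as a degenerate rejection with a warning.
- **Reliability**: ICC(2,1) — two-way random effects, absolute
  agreement, single measurement — from the ANOVA mean squares, the
  standard choice for two interchangeable raters; 95% CI by the
  McGraw & Wong F-distribution method. Cross-checked against an
  independent implementation in the test suite.
- **Sample size**: n = ⌈(z₁₋α/₂ · σ / w)²⌉ for estimating a mean to CI
  half-width w; with σ = 1.95 mm, w = 0.5 mm, α = 0.05 this gives 59.
- **Folded-normal mean**: E|X| for X ~ N(μ, σ²) in closed form; σ = 0
  degenerates to |μ|. Used to link signed and absolute cohort summaries.

## Synthetic data

### Meshes

The ulna analogue is a lofted closed tube: rings along a bowed centerline
with a bulbous proximal spherical cap (olecranon analogue, radius
`shaft_radius + olecranon_bulge`), a smoothstep taper to the shaft, a
flare to the distal hemispherical cap (dome analogue, radius
`dome_radius`), and pole vertices at both tips. It is *not* anatomically
faithful; it reproduces exactly the features the pipeline uses — two
extremal landmarks separated by the bone length, larger proximal girth,
a circular shaft cross-section.

Defaults (mm): total_length 260, shaft_radius 7, dome_radius 9,
olecranon_bulge 5, bow amplitude 1.5% of length (axis tilt from the
chord ≈ 1.7°, a subtle bow as in real ulnae), 80 mid-shaft rings × 32
points per ring, no surface noise, seed 0. Landmarks returned are the
exact noise-free tip positions; surface noise (i.i.d. Gaussian vertex
displacement, applied before mirroring so left/right remain exact
mirrors for equal parameters and seed) scatters the mesh around them.

The proximal (cap + taper, taper length 6·shaft_radius) and distal
(flare 4·shaft_radius + cap) regions have *fixed millimetre* dimensions;
changing total length stretches only the constant-radius mid-shaft. A
generated pair with an imposed difference (split symmetrically around
the base length, exact in ground truth) therefore has congruent end
regions, as real contralateral bones share epiphyseal shape while
differing in shaft length — and ground-truth recovery of the imposed
difference is well-posed. Bones shorter than the fixed end regions
(≈ 93 mm at default radii) are rejected.

### Cohorts

The simulator draws the patient-level signed difference from
N(signed_diff_mean, signed_diff_sd); defaults are the study conditions
of a 65-patient cohort: mean 1.02 mm, SD 2.98 mm, 75% female, 52%
non-dominant-side malunion. Ages are uniform on 18–80 (mean 49, SD ≈ 18;
only the cohort mean 47 (SD 17) and the 18–49/50+ split are published,
so the uniform shape is this package's choice). Observer readings are
the true difference plus independent N(0, observer_noise_sd²) noise
(default 0.1 mm, which reproduces the ICC > 0.99 regime against
between-patient SD ≈ 1.8–3 mm). Observer noise is applied to the final
measured difference, not to meshes — geometric and statistical test
surfaces are deliberately separate. In the written CSV, the adjudicator
column is filled only for flagged cases and picks the observer value
closer to the simulated truth. The CSV carries a per-patient
`ulna_length_mm` (the longer bone's true length) so relative differences
are computable downstream.

## Numerical choices

- Duplicate vertices are merged at 1e-6 mm on load (STL stores triangles
  independently); degenerate faces dropped. Meshes need not be
  watertight — the cut and fit operate on open contours.
- PLY is written with float64 properties by an in-package serialiser so
  round trips are lossless; ASCII STL keeps full precision. Binary STL
  is float32 by format definition (~3e-5 mm quantisation at 260 mm
  coordinates); this is far below measurement scale but above the 1e-6 mm
  round-trip guarantee of the other dialects.
- Circle fitting requires ≥ 3 non-collinear points (rank check on the
  algebraic system); cross-sections require ≥ 8 points within 1e-6 mm of
  the cut plane. When the cut yields several contours, the largest
  perimeter wins.
- Closest-point queries check the k = 20 nearest triangles by centroid;
  exact for reasonably uniform tessellations.
- All simulation randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated runs are bit-identical.

## Problem sizes

Default mesh resolution (~4,100 vertices, 8,200 faces per bone) resolves
imposed differences of 0–7.23 mm to within ~0.01 mm on noise-free pairs;
the test suite exercises reduced resolutions for speed where full
resolution is not the point. The replicate-cohort consistency analysis
uses 2,000 cohorts of n = 65, for which the mean absolute difference has
SE ≈ 0.22 per cohort and ≈ 0.005 across replicates.

## Limitations

- The synthetic ulna is a geometric analogue, not a statistical shape
  model: passing tests demonstrate correctness of the geometry and
  statistics pipeline under known ground truth, not segmentation-grade
  robustness on real CT surfaces (varying cortical texture, styloid
  geometry, segmentation artifacts).
- Alignment tolerances (2 mm) and the proximal correspondence fraction
  (0.5) are package defaults verified against synthetic ground truth,
  not clinically validated constants.
- Only lengthwise asymmetry is measured; rotational or radial asymmetry
  is out of scope, as is any modelling of the malunited radius itself.
- The relative-difference denominator (projected length of the longer
  ulna) is one reasonable definition; published reports often leave the
  denominator unspecified, so relative values are comparable only within
  a convention.
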