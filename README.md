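# ulnadiff

Measurement of bilateral ulnar length differences on 3D bone surface
models, with the cohort statistics used to report them.

## Why

In 3D-planned corrective osteotomy of a malunited distal radius, the
healthy contralateral radius is mirrored over the malunited one as a
template. Because healthy left and right forearms already differ in
length, the radii must first be corrected for length — and the standard
way to do that is to measure the left–right length difference of the
*ulnae*, which are unaffected by the radius malunion. `ulnadiff`
implements that measurement as a reproducible, automatable pipeline, plus
the statistics a reliability study of such measurements needs.

## The measurement

Given triangulated surface meshes of a patient's left and right ulna (STL
or PLY, millimetres):

1. **Mirror** the left ulna so both bones have the same chirality.
2. **Align** it rigidly to the right ulna from proximal to distal:
   landmark-guided initialization followed by iterative-closest-point
   (ICP) refinement with point-to-surface correspondences. Only rigid
   transforms are used — scaling would absorb the length difference being
   measured. Correspondences are restricted to the proximal half of the
   moving bone so the olecranons anchor the alignment and the distal
   separation (the measurand) is left free.
3. **Gate** the alignment: success requires the olecranon tips to overlap
   (default ≤ 2 mm) and the dome tips to coincide laterally (≤ 2 mm
   perpendicular to the axis); the along-axis dome separation is never
   penalised.
4. **Axis**: on the longer ulna, cut halfway between the olecranon tip
   and the dome tip, fit a least-squares circle to the cut contour, and
   run the measurement axis from the circle center to the dome tip.
5. **Measure**: the signed length difference is the difference of the two
   dome-tip projections on this axis, reported right-minus-left
   (Δ = p(dome_R) − p(dome_L); positive = right longer), together with
   the absolute difference |Δ| and the relative difference
   100·|Δ|/L, where L is the projected full length of the longer ulna.

Cohort statistics: two observers per patient, discrepancies > 1 mm
adjudicated by a third; ICC(2,1) (two-way random effects, absolute
agreement) with a 95% F-based CI for inter-observer reliability; Welch
t-tests across age (18–49 vs 50+), sex, and malunion-side subgroups;
Lilliefors-corrected Kolmogorov–Smirnov normality checks; the
CI-half-width sample-size formula n = ⌈(z₁₋α/₂·σ/w)²⌉; and the
folded-normal mean E|X| = σ√(2/π)·e^(−μ²/2σ²) + μ(1 − 2Φ(−μ/σ)) linking
signed and absolute summaries.

Because no public mesh dataset accompanies this kind of study, the
package ships a first-class synthetic module: parametric ulna-like meshes
(bowed tube, olecranon-like proximal bulge, hemispherical distal dome)
with exact ground-truth landmarks and imposed length differences, and a
cohort simulator with a configurable signed-difference distribution,
demographics and observer noise.

## Worked example

```bash
$ ulnadiff simulate-meshes --diffs "0,3.0,-7.23" --out scratch/meshes
$ ulnadiff measure --manifest scratch/meshes/manifest.csv --out scratch/meas.json
INFO tolerances: icp_tol=0.0001 mm, olecranon_tol=2 mm, dome_lateral_tol=2 mm
INFO S001: signed +0.000 mm, abs 0.000 mm (0.00%), icp rms 0.0000 mm, alignment ok
INFO S002: signed +2.993 mm, abs 2.993 mm (1.14%), icp rms 0.0037 mm, alignment ok
INFO S003: signed -7.223 mm, abs 7.223 mm (2.74%), icp rms 0.0082 mm, alignment ok
```

Each record reports the signed right-minus-left difference recovered from
the mesh pair (here within ~0.01 mm of the imposed ground truth — S002
was generated with +3 mm, S003 with −7.23 mm; the small shortfall is
binary-STL float32 quantisation plus residual registration error), the
ICP residual, and whether the alignment gate passed.

```bash
$ ulnadiff simulate-cohort --seed 2 --out scratch/cohort.csv
$ ulnadiff summarize --cohort scratch/cohort.csv --out scratch/summary.json
Variable              N (%)         Abs diff mm (SD)    p       Rel diff % (SD)     p
------------------------------------------------------------------------------------------
N                     65            2.53 (1.89)                0.97 (0.73)
Age                                                     0.73                        0.76
  18-49               35 (54%)      2.45 (1.82)                0.95 (0.71)
  ...
ICC(2,1): 0.999 (95% CI 0.998-0.999); KS normality p = 0.72; adjudicated: 0
```

The simulated cohort (n = 65, signed differences N(1.02, 2.98) mm, 0.1 mm
observer noise) yields a mean absolute difference near the folded-normal
population value of ≈ 2.52 mm and an ICC above 0.99, the regime expected
when observer noise is an order of magnitude below between-patient
variability.

The same workflows are available as library calls: `generate_pair`,
`measure_pair`, `simulate_cohort`, `summarize_cohort`.

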