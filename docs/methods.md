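# Methods

This note documents the measurement model, the synthetic "stated world" the
tests run against, the numerical choices, and the limits of what a green test
establishes.

## Coordinate conventions

All lengths are millimetres, all angles degrees. Axial stations are measured
from the greater-trochanter (GT) apex along the femoral anatomical axis
(FAA), increasing distally. Every version angle is a signed in-plane angle
against the posterior condylar axis (PCA) in the plane normal to the FAA,
with the sign convention *positive = anterior rotation* for both sides: the
in-plane angle is taken counter-clockwise about the distal FAA direction for
right femurs and flipped for left femurs (equivalent to mirroring left
femurs into a right-handed convention and reporting unmirrored values).
Undirected lines are canonicalized to a non-negative PCA component, so line
angles live in (−90°, 90°].

## Anatomical axis (FAA)

The FAA is the total-least-squares 3D line through the centroids of
algebraic (Kåsa) least-squares circles fitted to shaft cross-section
outlines, sampled at 1 mm spacing over 10–90% of femoral length (the
lesser-trochanter center CLT to the knee center, itself the midpoint of the
epicondyles). Two equivalent phrasings of this axis exist (fitting cylinder
vs. circle-centroid line); the centroid-line form is implemented because it
stays well defined for bowed shafts. The fit is bootstrapped: a coarse pass
slices normal to the CLT→knee-center chord (4 mm spacing) to seed the axis,
and the final pass re-slices normal to the fitted line at 1 mm. Fewer than
10 valid shaft circles raises an insufficient-geometry error. The Kåsa fit
is not iteratively refined — shaft outlines are near-circular and the
algebraic bias is negligible at that eccentricity; input points are centered
before solving so the fit is scale- and translation-stable.

## Slice levels and the five parameters

Proximal femoral height H is the along-axis distance from the GT apex to the
CLT; measurement stations sit at 33% H (MFN), 66% H (LFN) and at the CLT.

* **FA-MFN / FA-LFN** — the neck's cortical bisector: midpoints of
  anterior/posterior boundary pairs are sampled at 41 stations across the
  central 90% of the section's principal (long) direction, and a
  total-least-squares line through them gives the bisector. For an exact
  ellipse this reproduces the major axis; sections with a principal-axis
  ratio below 1.05 carry an `UnstableMeasurementWarning` but still return a
  value.
* **FA-CLT** — the canal's longest transverse diameter: the maximum Feret
  chord of the endosteal contour (convex-hull accelerated; ties broken by
  traversal order, near-circular canals warn). At the CLT station the
  endosteal loop is used and the periosteal loop ignored.
* **CF-LFN / CF-CLT** — the calcar femorale reads, in cross-section, as a
  tongue of bone protruding into the canal lumen. Detection: boundary points
  deviating inward from the canal contour's convex hull by more than 1.5 mm
  form candidate runs; the ridge is *present* when its extent into the canal
  (the maximum hull deviation) reaches 3 mm. Both thresholds are
  configurable. The ridge "length" is deliberately the protrusion extent,
  not the boundary arc length of the notch — a 2 mm tongue has an arc of
  ~5 mm and would otherwise defeat the threshold's purpose. The ridge line
  is fitted to the crest of the protrusion (points within 0.35 mm of the
  maximum deviation, with up to three residual-trimming passes at 0.3 mm) so
  that wall-shape-dependent flanks cannot bias the orientation.

Absence of the ridge at the LFN level is a valid result and defines the
non-CF group.

## Registration and stem anteversion

The postoperative model is registered to the preoperative femur by rigid
ICP: nearest-neighbour correspondences against the fixed model's vertices,
Kabsch updates, centroid + principal-axes initialization (best of the four
proper sign flips), stopping when the RMS improves by <1e−6 mm or at 200
iterations (non-convergence warns, it is not fatal). Implant faces labeled
`STEM_NECK` are excluded from both clouds, since the implant has no
preoperative counterpart. Correspondence is point-to-vertex rather than
point-to-triangle; on the dense meshes used throughout, displaced copies
share exact vertex correspondences and recovery error is far below the
0.1°/0.1 mm acceptance bound. The stem neck axis is the total-least-squares
3D line through the labeled stem-neck vertices after transformation into the
preoperative frame; its projected line angle against the PCA is the stem
anteversion. Preoperative-only measurement is supported (stem fields absent)
so the prediction equations can run before surgery.

## Synthetic femurs — the stated world

The generator lofts analytic cross-sections along a straight axis: an
elliptical neck (16×10 mm) whose midline rotates linearly between the
specified MFN and LFN anteversions; an elliptical canal (semi-major 8.5 mm,
axis ratio ≥ 1.05, default 1.6) rotated to the specified torsion; a circular
diaphysis (radius 13.5 mm) and a condylar flare (35×22 mm) carrying the
knee landmarks; annular caps close the outer and endosteal walls into a
single watertight genus-1 surface. Default parameter values are the CF-group
cohort means (neck anteversion 18.5/37.6°, canal torsion 52.0°, CF angles
35.9/51.5°, stem 26.7°); H defaults to 75 mm and femoral length to 300 mm.
Meshes are deterministic functions of the spec (no randomness), so identical
specs are byte-identical on disk.

The calcar ridge is carved as a plate lying flat on the endosteal wall —
anchored where the wall tangent parallels the requested ridge direction
(posteromedial candidate), free edge 8 mm, protruding `cf_depth` (default
5 mm) into the lumen. This keeps the notch away from the canal major-axis
endpoints, so the Feret measurement survives, **provided the CF angle stays
within ~30° of the canal torsion**. That envelope is anatomically motivated
(the calcar forms the canal's posterior wall, and the two orientations track
each other in real cohorts); the recovery sweeps therefore draw CF angles as
torsion + U(−25°, 25°), clipped to 10–70°. Specs outside the envelope are
legal but their FA-CLT/CF recovery degrades.

The postoperative generator reuses the femur and adds a separate closed
stem-neck cylinder (radius 5.5 mm, length 30 mm, 40° elevation above the
slice plane) whose faces are labeled `STEM_NECK`; the whole model is then
moved by the requested rigid displacement to force the registration path.
The retained native neck is a deliberate simplification — registration
excludes the implant by label either way.

What a green geometric test establishes: the slicing, axis, angle, detection
and registration code recovers known section-level ground truth on smooth,
symmetric, noise-free bone-like shapes. It does not establish robustness to
segmentation noise, cortical thinning, osteophytes, metal artifacts, or
real calcar morphology.

## Synthetic cohorts

Cohort tables draw per-group predictors from truncated normal distributions
at the published group means/SDs (CF: five parameters; non-CF: three), with
truncation to the anatomically plausible (−20°, 100°). The underlying
parameters are moment-matched so the *truncated* distribution has exactly
the requested mean/SD (plain truncation would shrink the non-CF FA-CLT SD
by ~3%, violating the 2% moment contract). The response is the group linear
model — CF: 0.464·FA-CLT + 0.559·CF-LFN − 17.497; non-CF: 0.749·FA-LFN −
1.433 — plus Gaussian noise whose SD (CF 5.78°, non-CF 7.55°) is derived
from the published multiple R (0.870 / 0.864) under independent predictors:
`noise_sd = signal_sd·sqrt(1/R² − 1)`. Predictors default to independent
draws; a per-group correlation matrix can be supplied, because published
marginal correlations imply substantial inter-predictor correlation
(ρ(FA-CLT, CF-LFN) ≈ 0.65 is consistent with the printed marginal and
multiple correlations). Crowe grades are drawn at the published group
proportions (CF 18/2/1, non-CF 4/6/3 across I / II–III / IV), and
demographics at the published group means.

A consequence worth stating: with noise calibrated to R = 0.870 at n = 21,
the forward-selection entry of FA-CLT after CF-LFN has ~88–92% power, so
"both intended predictors selected first" holds in ≈88% of cohorts, not
≥90% — and under the correlated-predictor world the entry t of FA-CLT drops
to ≈2.3 (matching its published borderline p of 0.034), i.e. ≈60% power.
The corresponding acceptance test asserts the stated ≥90% and is expected
to fail; we left it red rather than tune the noise or the threshold.

## Statistical stage

* Group contrast: pooled-variance Student t (the pooled form reproduces the
  published t statistics from printed summaries; Welch does not), two-sided.
* Categorical contrast: Pearson chi-squared without continuity correction,
  despite small expected counts — the printed Crowe p (0.004) is slightly
  smaller than this statistic's p (≈0.005); the discrepancy is recorded, not
  "fixed".
* Association: Pearson product-moment R with the t-transform p-value.
* Selection: pure forward stepwise (no removal), entry criterion p < 0.05 on
  the entering coefficient, ties broken by larger absolute partial
  correlation; no entering candidate yields the intercept-only fit.
* Prediction: the group-appropriate equation (fitted or built-in published
  coefficients); absolute errors summarized per group as mean ± SD.
* Reliability: observer variation is emulated as isotropic Gaussian jitter
  of the landmark coordinates (default 1 mm) before re-measurement, because
  no observer protocol is specifiable for synthetic data; intra-observer r
  correlates two repeats of one simulated observer across models,
  inter-observer r correlates two observers' per-model means.

`StemAnteversionModel.fit()` packages the whole stage; its results object
carries the group equations, side tables, a `summary()` text table, and
`predict()` for new hips.

## Numerical choices and degenerate inputs

* Plane/mesh sections nudge the plane by 1e−6 mm when a vertex lies exactly
  on it, making slices through loft rings robust.
* Contours are resampled uniformly by arc length before any moment or
  hull computation (512 points for sections, 384 for calcar detection) to
  remove sampling-density bias.
* Collinear circle points, coincident condyles, zero-variance correlations,
  rank-deficient designs, swapped GT/CLT landmarks, and absent structures
  raise typed errors (`DegenerateGeometryError`, `OrientationError`,
  `MissingStructureError`, …) rather than returning garbage.
* Mesh ring resolution trades accuracy for speed: at the default 160
  boundary points per ring, mean FA recovery error is ≈0.2°; at 96 points
  FA-CLT errors can exceed 1° because the Feret chord quantizes.

## Known limitations

* Schematic anatomy: straight shaft, centered neck, no cortical-thickness
  variation; measurements depending on those features are untested.
* Point-to-vertex ICP underestimates registration error on coarse meshes.
* The reliability emulation captures landmark-placement variability only,
  not slice-selection or boundary-tracing variability of human readers.
* Prediction-error magnitudes from synthetic cohorts (≈4–6° mean absolute
  error) bracket but cannot reproduce patient-data values, which depend on
  unavailable raw measurements.
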