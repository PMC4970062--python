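# Methods

This note documents the models, conventions and numerical choices behind
`kiwigrade`, and what the synthetic experiments do and do not demonstrate.

## Measurement model

A fruit lies on 1 mm coordinate paper and is photographed from directly
above. The image chain is deliberately classical:

* **Grayscale.** NTSC luma, `gray = 0.299 R + 0.587 G + 0.114 B`, rounded
  half-up to an integer in [0, 255]. Rounding half-up (rather than
  banker's rounding) is a documented convention; any fixed deterministic
  rule would do.
* **Thresholding.** Otsu's criterion over the 256-bin histogram. We define
  the two classes as `{pixel < t}` and `{pixel ≥ t}` — the same convention
  binarization uses, so the returned threshold is directly applicable — and
  minimize the within-class sum of squared deviations. Ties are broken
  toward the lowest threshold. The implementation uses cumulative histogram
  moments; the test suite checks it against a brute-force scan of all 256
  thresholds on every image class we generate. A constant image has no
  threshold and raises an error.
* **Binarization boundary.** A pixel *equal* to the threshold becomes
  foreground (white), matching the "values below the threshold become
  black" reading.
* **Area filtering.** Connected components of white pixels
  (8-connectivity by default — robust to single-pixel bridges along hairy
  boundaries) strictly smaller than 1/20 of the largest component are
  removed. A component exactly at the 1/20 boundary is kept.
* **Size extraction.** The axis-aligned bounding rectangle of the white
  pixels gives `PL` (longer side) and `PW` (shorter side); the white count
  gives `PPA`. Assigning the *longer* extent to length enforces
  `L ≥ MaDES`, which holds for kiwifruit (MaDES/length ≈ 0.82 on average).
  The rectangle is axis-aligned; fruit are assumed roughly image-aligned,
  as on a sorting line. An optional rotation is available in the synthetic
  renderer to quantify the (small) bias this causes.
* **Calibration.** `RA` is pixels per mm² of the coordinate paper. It can
  be supplied directly (`--ra`) or detected: grid lines appear as periodic
  dark minima of the row/column mean-intensity profiles; the least-squares
  slope of peak position against peak index gives the pitch in pixels,
  robust to the ±0.5 px quantization of line positions at fractional
  pitches (e.g. 7.5 px/mm recovers RA = 56.25 to ~0.1%). Automatic
  detection uses the top border strip of the fruit image, which shows bare
  paper.
* **Physical units.** `L = PL/√RA`, `MaDES = PW/√RA` (mm),
  `PA = PPA/RA` (mm²; model interfaces use cm²). An optional
  `hair_offset_mm` (default 0) can be subtracted from both linear sizes to
  compensate the systematic ~1 mm oversize caused by the hair fringe; it is
  off by default because the reference calibration models were fitted to
  uncorrected measurements.

Expected accuracy: pixel discretization bounds the linear-size error by
about one pixel (`1/√RA` mm) per side; the pixel-count area is unbiased
with sub-percent error at `RA ≥ 9`.

## Hidden-size estimation

The thickness `MiDES` is invisible from above, so it is estimated from the
measurable parameters `(W, L, MaDES, PA)` by a linear model; fruit volume
is estimated the same way. The built-in coefficients are a published
calibration for 'Hayward' kiwifruit (intercepts −2.36 mm and −2.69 cm³;
see README). Both built-ins carry all four printed coefficients even though
`PA` is statistically insignificant in the MiDES model and `PA`/`MaDES` in
the volume model — the printed four-coefficient form is used as-is rather
than inventing unprinted refit coefficients; the `PA` terms are numerically
negligible (−3.71×10⁻⁴ mm and 5.47×10⁻⁵ cm³ per cm²).

The stepwise fitter (`fit_smlr`) uses forward entry / backward removal on
coefficient p-values with defaults `alpha_enter = 0.05`,
`alpha_remove = 0.10` (the conventional choice; both configurable).
Candidates whose addition makes the design singular are skipped. The final
model is an ordinary least-squares refit on the selected set (residual
df = n − k − 1); the tests verify it matches an independent `lstsq` refit
to 10⁻⁸ relative. A constant response returns the intercept-only model
directly, since p-values are undefined at zero residual variance. Note on
property tests: with two pure-noise candidates and `alpha_enter = 0.05`,
the family-wise false-entry probability is ≈ 10%, so exact-support
recovery experiments use `alpha_enter = 0.01` (≈ 2% family-wise), a
standard multiplicity consideration rather than a change to the defaults.

## Grading and confusion analysis

Grades follow the weight/MMR rule with inclusive thresholds ("90 g minimum",
"0.8 or greater"): Extra (≥ 90 g, MMR ≥ 0.8), class I (≥ 70 g, ≥ 0.7),
class II (≥ 65 g), otherwise Reject. Grading is monotone in both weight and
MMR, and any fruit under 65 g is Reject regardless of shape.

`ConfusionTable` counts estimated × actual classes. The classification rate
is the diagonal share; *overgrading* counts fruit whose estimated class
exceeds the actual one (the costly error direction);
`misgrade_rates_by_actual` gives the per-actual-class misgrade percentages.

## Ratio-space reclassification

MiDES estimation error is not symmetric across fruit shapes: flattened
fruit (large MaDES, small MiDES) lie below the pooled linear MiDES trend,
so the model overpredicts their thickness and overgrades them. Such fruit
are geometrically distinctive — relatively low length/MaDES and low
length/PA — so fruit graded Extra or class I are re-examined in the
(length/MaDES, length/PA) plane:

* estimated Extra: one line separating actual Extra from actual class I;
* estimated class I: a first line splitting off actual class II, then a
  second separating actual Extra from actual class I;
* estimated class II and Reject pass through unchanged (their weight bands
  make them reliable).

Lines are equal-covariance linear discriminants (scikit-learn LDA) fitted
on labeled validation fruit, with **empirical class priors**: the boundary
is then the error-minimizing Bayes rule for the training groups, which
guarantees reclassification does not trade many majority-group fruit for a
few minority recoveries. A point exactly on a line takes the lower class
(conservative grading; configurable by editing the line's side classes).
Lines serialize to JSON (either `a·x + b·y + c = 0` with side classes, or
slope/intercept with upper/lower classes), so a packing line can apply a
frozen configuration without refitting.

## Synthetic data

The generators define the conditions under which the package is validated.

**Single-fruit renderer.** The silhouette is a superellipse
`|x/a|ⁿ + |y/b|ⁿ = 1`. The default exponent is `n = 5`: the reference
population's mean PA/(L·MaDES) ≈ 0.945 corresponds to `n ≈ 4.8`, i.e. real
kiwifruit silhouettes are much fuller than ellipses (π/4 ≈ 0.785). The
hair fringe is an outward-only perturbation
`h·(1 + sin(2π f θ + φ))/2` with amplitude `h` (default 0.3 mm; the real
hair layer is ≈ 0.5 mm) and frequency `f` = 0.5 cycles/degree, so the
measured length and MaDES exceed the hairless size by ≈ 2h — reproducing
the oversize bias of real images in magnitude and direction. Ground truth
(length, MaDES, PA) is computed from the continuous boundary curve by dense
quadrature before rasterization. The scene adds the calibration grid
(dark 1 px lines), optional bright noise blobs outside the fruit, and
Gaussian pixel noise (foreground/background separation is validated to be
≥ 3 noise SDs). Everything is deterministic under a fixed seed.

**Population sampler.** Per class, `(W, L, MaDES, MiDES)` are drawn from a
truncated (positive-orthant) multivariate normal with configurable marginal
moments and a latent correlation matrix; `PA` and `V` are derived from
`L·MaDES` and `L·MaDES·MiDES` products with 5% multiplicative noise and
then affinely standardized to the class marginal moments. Defaults:

* Marginal moments default to the published 'Hayward' reference rows
  (N = 490 across Extra/I/II/Reject; the "Total" row is available for
  single-population draws, whose sample means reproduce the reference
  means to within sampling error).
* The correlation matrix is not published; the default sets
  corr(L, MaDES) = 0.93 and corr(MaDES, MiDES) = 0.90, chosen so the
  within-class spreads of length/MaDES (≈ 0.05) and MMR (≈ 0.05) match the
  published ratio statistics. This is a package convention, not a measured
  quantity.
* Classes I and II are two-morph mixtures: a *regular* morph plus a
  *(semi-)flattened* one (31% of class I: ≳ 90 g with MMR between 0.7 and
  0.8; 20% of class II: ≳ 90 g with MMR < 0.7), matching the reported
  composition of those classes. The flattened morphs' MiDES sits ~3 mm
  below the pooled linear trend for their weight/length, which is exactly
  what makes the estimator overgrade them — and their low length/MaDES
  makes them separable in ratio space. Sub-moments are calibrated so each
  mixture approximates the published class row; the class II mixture's
  mean weight (≈ 74 g) deliberately undershoots the published 80.8 g,
  whose huge SD (28.2 g) reflects a composition that rule-consistent
  regular fruit cannot reach.
* Class labels are *recomputed* from each sampled fruit's weight and true
  MMR, so a fruit drawn "as" class I may legitimately be actual Extra;
  this boundary traffic is part of what the fixtures test.

**Validation fixtures.** `make_validation_fixture` renders N fruit whose
superellipse exponent is solved per fruit from its sampled PA/(L·MaDES)
(clamped to the feasible [π/4, ≈0.975] range), with weights and
ground-truth CSVs. Fruit within a small margin of a grade boundary
(|MMR − {0.7, 0.8}| < 0.02 or weight within 2 g of {65, 70, 90}) are
resampled so that true classes are unambiguous under sub-pixel measurement
error — a fixture-design choice, not a claim about real populations.

**End-to-end experiment.** `run_grading_experiment` mirrors the reference
study design: 490 fruit, 140 for calibration, 350 for validation; Gaussian
measurement noise (0.4 mm on linear sizes, 0.4 cm² on PA) emulates imaging
error when images are not rendered; the MiDES model is fitted by stepwise
regression on the calibration split, validation fruit are graded from
estimated MMR, and discriminant lines are fitted and applied on the
validation set (resubstitution, as in the reference workflow). Typical
results at these settings: initial classification rate ~82–88% with
overgrading ~11–17%, improving by ~3–7 percentage points after
reclassification. The experiment also runs image-based (render → measure →
grade) at smaller N; at N = 200 the improvement is positive on average but
noisy, so tests aggregate a few seeds.

## What the synthetic results do and do not show

Passing tests demonstrate internal correctness (threshold optimality,
calibrated size recovery, selection behavior of the stepwise fitter,
monotone grading, error-reducing reclassification under the generated
conditions). They do not validate the built-in coefficients against real
fruit, do not reproduce the reference study's real-data correlation
figures (R² of 0.82/0.95/0.96/0.98 and the 2.5% volume error require the
original 490 fruit), and the synthetic reclassification gain is smaller
than the published one because the generated ratio clouds overlap more
than the real figures suggest. The published confusion *counts*, by
contrast, are exact inputs, and all rates derived from them (84.6%, 11.7%,
per-class misgrade rates, 98.3% after the reported reassignments) are
reproduced exactly.

## Known limitations

* Single fruit per image; no conveyor tracking, lighting correction, lens
  distortion, or perspective-size correction.
* Grid detection assumes a reasonably regular grid and a fruit-free border
  strip; supply `--ra` when that fails.
* The bounding rectangle is axis-aligned; strongly rotated fruit oversize
  both dimensions.
* The hair model is sinusoidal, not stochastic filament rendering; it
  reproduces the first-order oversize bias only.
* Reclassification quality depends on the validation set used to fit the
  lines; frozen line configurations should be refitted per cultivar and
  season.
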