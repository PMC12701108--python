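# Methods

This note records the model choices, parameters and numerical conventions
behind `dcecad`, and what the synthetic studies do and do not demonstrate.

## Coordinates and intensities

`X` is the row index (anterior at row 0), `Y` the column index; all indices
are 0-based and crop-window bounds are inclusive (pixel width
`y_max − y_min + 1`). Raw intensities are arbitrary units; every stage
works on unit-normalised floats (`to_unit_range`), and raw integers are
touched only at I/O. Subtraction images are computed on raw stack
intensities and clipped at zero before normalisation — the clipping
convention matches how subtraction images are displayed; the order
(subtract, then normalise) is a package choice since either order only
rescales the Otsu input.

## Breast cropping

"Background" is deliberately loose in MR practice; the default is a robust
estimate from the four 8×8 corner patches: the 99th percentile plus 6
IQR-derived standard deviations. Magnitude images clip air noise at zero
(a half-normal distribution), which breaks MAD-based scales — the
percentile/IQR form handles both clipped and noise-free backgrounds (a
zero background yields level 0, so any positive pixel is foreground).
Bounds come from Phase 0, which shows the full anatomy; one window crops
Phase 0 and both subtraction images. Even image widths use the lower
median column. The posterior bound is the chest depth at the median column
plus a 10-px margin, clamped to the frame.

## Pre-processing

CLAHE with an exponential target: per tile (8×8 grid), the 256-bin
histogram is clipped at `clip_limit` (default 0.01) × tile pixel count
with uniform redistribution of the excess, and values are mapped through
the inverse CDF of an exponential distribution truncated to [0, 1] with
decay `alpha = 0.4`; tile mappings are blended bilinearly. With desk-scale
tiles (a few hundred pixels across 256 bins) the clip is aggressive and
the mapping is close to a global monotone stretch — that is inherent to
the parameterisation, not a defect. The alternating sequential filter
applies grayscale opening-then-closing for each disc radius in (1, 2):
the smallest strictly increasing pair, which removes speckle while
preserving structures at and above the 15-px minimum lesion size. Reading
"two sequential openings and closings" as two open–close pairs (rather
than open–close followed by close–open) is a documented interpretation.

## Multilevel Otsu

Four thresholds (five classes) maximise between-class variance over the
256-bin histogram. The maximiser is exact: the objective decomposes into
per-class interval scores `(Σ x·p)² / Σ p`, optimised by dynamic
programming over cut positions — equivalent to exhaustive search over all
threshold tuples, which the tests verify by brute force on 16-level
images. Ties resolve deterministically (first maximiser in the backtrack).
The top class uses strict inequality (`img > t_max`); ties at the
threshold fall to the lower class. The histogram is taken over the cropped
region only, since cropping precedes thresholding in the pipeline. A
lesion counts as "detected" when ≥ 50 % of its truth pixels lie in the
intersection mask — an evaluation convention, as overlap is otherwise
unquantified.

## Rule stage

"Size" is interpreted as component pixel count; 15 px at 654.762 µm/px is
9.82 mm, commonly rounded to the 10-mm conventional detectability limit.
(An alternative reading — 15 px as a maximum linear dimension — is exposed
via configuration but off by default.) Eccentricity is that of the
second-moment ellipse. Boundaries follow the wording exactly: reject
strictly below 15 px or strictly above 0.95. Components are 8-connected.

## Control ROIs

Mirroring about the frame midline followed by re-inversion about the
mirrored region's own centroid column composes — two reflections about
parallel vertical axes — into a horizontal translation by
`2·(m − centroid_col)`, rounded to the nearest pixel and applied as an
integer shift, which conserves the pixel count exactly. On synthetic data
the radiologist's inspection of controls is replaced by a ground-truth
overlap test with ±3-px row jitter (up to 10 tries); on real data controls
are emitted for human review.

## Features

All ROIs are dilated by a 1-px disc before feature extraction to absorb
minor patient movement between Phase 0 and the post-contrast phases.
GLCM statistics use masked pair counting — only pixel pairs with both
endpoints inside the (dilated) ROI contribute — so surrounding tissue
cannot leak into the texture description; intensities are quantised to 8
levels over the ROI's own min–max range, matrices are symmetric and
normalised, and the six statistics (contrast, correlation, energy,
homogeneity, entropy in bits, inverse difference moment) are averaged over
the four directions per distance (d = 1, 2). A constant ROI returns the
degenerate single-cell statistics with correlation reported as 0 (with a
warning). The ring for the contrast ratios grows the ROI by a 4-px disc
(matching the typical area-to-perimeter ratio of detected lesions) and
subtracts the ROI. The default vector is 12 GLCM + CON + C = 14 entries —
the only listed combination consistent with the stated count — with ROI
mean/SD available as optional extras.

## Selection and classification

ReliefF iterates over all samples with k = 10 neighbours, Manhattan
distance on min–max-scaled features and class-prior-weighted misses;
weights lie in [−1, 1] and are logged for comparison. The elimination
itself is a backward wrapper: at each step the single feature whose
removal most decreases 5-fold stratified CV misclassification of the
wrapped Gaussian-kernel SVM (fixed fold seed) is dropped; the search stops
when no removal strictly decreases the criterion.

The FFBPN has one hidden tanh layer (6 or 10 units), two tanh outputs
(targets ±1, prediction by the larger output) and MSE loss, trained by
Møller's scaled conjugate gradient with early stopping (patience 6
validation failures, max 1000 iterations) on a stratified 65/15/20
train/validation/test split, re-drawn for each of five repeats; three
random restarts keep the weights with the best validation MSE, guarding
against poor local minima of the small network. Training folds are SMOTE-
balanced. The SVM uses stratified five-fold CV with SMOTE applied inside
each training fold only — synthetic points never reach a validation fold —
and tunes the kernel coefficient and class weights on an inner 3-fold
grid; pooled out-of-fold predictions yield the confusion metrics and
trapezoidal ROC/AUC. SMOTE interpolates uniformly between a minority
sample and one of its 5 minority nearest neighbours until counts equalise.

McNemar tests condition on the discordant predictions (b: first classifier
right and second wrong; c: the reverse), Binomial(b+c, ½) under the null.
The one-sided "A better" p-value is `P(X ≥ b)`; mid-p counts half the
observed outcome's mass; the asymptotic variant is provided for
completeness. `b + c = 0` returns p = 1 (flagged degenerate). Repeat
metrics are reported as mean ± SD alongside the last repeat's counts.

## The phantom generator

The generator emulates the image structure the pipeline depends on, at
256×256 with 1 pre- + 6 post-contrast phases:

* **Anatomy** — two half-disk breasts (radii ≈ 0.19–0.21 of the frame) on
  a chest band at ≈ 39 % depth, a thorax body and an enhancing heart-like
  disc behind it; air background. The chest band spans the midline so the
  median-column depth scan used by the cropping stage is exercised.
* **Kinetics** (fraction of peak at post-phase p): persistent
  `0.78 + 0.0366·p` (strictly rising), plateau `min(0.9 + 0.1(p−1), 1)`,
  washout rising to 1 at p = 2 then `1 − 0.12(p−2)`. Persistent lesions
  are near their slowly-rising plateau by 2–3.5 min, as type-I curves are.
* **Amplitudes** — per-slice base peak enhancement U(0.44, 0.55) with
  ±8 % per-lesion jitter: amplitudes within one exam share injection and
  acquisition factors, so they are correlated; between-slice spread
  remains. Vessels enhance early (plateau curve) at strengths overlapping
  the lesions' — that overlap is what makes them confounders — and are
  4–5 px wide, 25–40 px long, nearly straight random walks, so their
  segmented components stay above 4:1 elongation (eccentricity > 0.95).
* **Background parenchymal enhancement** — a patchy smooth field up to
  ≈ 0.16 peak, rising over the first three post phases; a real DCE-MRI
  phenomenon that also gives the five-class Otsu stage a mid-intensity
  population to absorb its lower thresholds.
* **Noise** — additive Gaussian, SD 0.01 of the unit intensity scale,
  iid per phase, clipped at zero. Gaussian (not Rician) is a documented
  simplification; at this magnitude the detectability invariant (lesion
  subtraction means above the 95th percentile of healthy breast tissue at
  phases 2 and 3) holds by construction.

Phase 0 carries smooth parenchymal texture and slightly brighter, rougher
lesion texture, so lesion-vs-control classification has signal on the
pre-contrast image, as it does in practice.

The default 20-slice benchmark derives per-slice seeds from one master
seed (`SeedSequence.spawn`), draws 1–3 lesions per slice spanning ≈ 9–80 px
and 1–2 vessels, and forces the first slice's lesions below 15 px so the
size rule is always exercised.

What passing phantom tests shows: the stages implement their contracts —
cropping covers the breasts, segmentation recovers every sufficiently
enhancing region ≥ 15 px, the rules reject elongated and small components,
control construction conserves shape and area, and the classification
stack separates classes that are separable. What it does not show:
clinical performance. The phantom has none of the anatomical variability,
bias fields, motion, Rician noise or histological diversity of patient
data, and its lesions are separable from parenchyma by construction, so
perfect phantom metrics are integrity checks only.

## Classifier-recovery fixture

The classification stack is validated on two-class Gaussian feature clouds
(n = 400, 8 features, one informative) whose class means sit d′ = 4
standard deviations apart, with samples re-drawn across the midpoint
hyperplane so the sample is *linearly separable* by construction. Without
truncation, d′ = 4 leaves ≈ 2.3 % Bayes error and an 80-sample test split
fails a 95 % per-repeat accuracy bound stochastically even for the optimal
classifier; the truncated clouds make the recovery bounds limited by
estimation rather than Bayes error. The label-permutation null (20
shuffles) checks that the cross-validated AUC collapses to 0.5 when the
labels carry no signal.

## Problem sizes

Default study sizes — a 20-slice benchmark, 256×256 frames, n = 400
recovery samples, 5 CV folds, 5 network repeats, 3 restarts, 20
permutations — were chosen so the full suite and the acceptance script
each complete in minutes on one CPU while keeping every per-stage check at
the scale its contract describes.

## Known limitations

* Slice-based only; no 3-D volumes and no inter-phase registration (the
  feature image is Phase 0, so registration error is absorbed only by the
  1-px dilation).
* The cropping procedure implements the literal four-step scan; a passing
  mention of combining the scan with image rotations has no described
  algorithm and is not implemented.
* Kinetic and morphological feature families beyond GLCM + ring contrast
  are out of scope, as is benign/malignant discrimination.
* DICOM support covers multi-frame files with frames ordered pre-contrast
  first; pixel spacing defaults to 654.762 µm/px when absent (warned).
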