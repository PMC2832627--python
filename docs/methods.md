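# Methods

This note records the models, algorithms and numerical choices behind
`seroarray`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real screens.

## Measurement model

A protein macroarray screen produces, per serum, an 8-bit grayscale scan
of a membrane carrying thousands of protein spots in duplicate at known
grid positions. Spots are *dark* features on a brighter, noisy background:
stronger serum reactivity → deeper spot. The quantification target is the
spot's mean depth below background, reported per antigen as an integer in
the 0–255 grayscale range.

The synthetic generator emulates exactly this structure. Per serum *s* and
antigen *a*:

    depth[s, a] = scale_s · (base_a + effect · informative_a · group1_s + ε)

- `base_a ~ Exponential(depth_scale)` (default scale 40): most antigens
  weakly reactive, a few strong — the sparse-reactivity character of
  seroreactivity screens. Only the 0–255 range is externally fixed; the
  exponential shape is this package's choice.
- `effect` (default 30) shifts a fraction `frac_informative` (default
  0.05) of antigens in group-1 sera — the planted disease signal.
- `ε ~ N(0, noise_sd²)` (default sd 5) is per-profile measurement noise.
- `scale_s ~ LogNormal(0, σ=0.15)` is a per-serum multiplicative array
  effect (membrane batch, serum dilution, scanner gain) — the nuisance
  quantile normalization must remove.
- Depths are rounded half-up and clipped to [0, 255].

Rendered scans draw each depth as a hard disc (radius 3 px, pitch 10 px by
default; optional Gaussian edge softening) at both duplicate positions on
a background of level 200 with a linear horizontal gradient, rotate the
scene by a configurable small angle (bilinear, about the image centre),
add Gaussian pixel noise, and re-quantize to 8-bit integers. Depths
exceeding the local background clip to black with a warning; recovery
statements therefore compare against `min(depth, background)`.

Default group sizes are 47 vs 80 sera and the default panel is 1827
antigens on 16 subgrids of 256 spots — the scale of a mid-size lung-cancer
seroreactivity study. All geometry (pitch, radius, margins, subgrid
arrangement) is configurable and none of it is claimed to match any
particular physical array.

**What the generator does not emulate:** bacterial expression variability,
spot morphology defects (comets, doughnuts, merged spots), spatially
correlated background, scanner point-spread physics, or antigen–antigen
reactivity correlations. Passing recovery tests show the pipeline is
correct under the stated model, not that it is robust to every artifact of
real membranes.

## Image quantification

Stages run in this order: rotation correction → edge crop → grid
segmentation → per-spot clustering on the **raw** image → optional area
adjustment → black top-hat of the whole raw image → mean of the
**processed** image over each spot's foreground → duplicate averaging.

**Rotation correction.** The estimate maximizes a grid-alignment criterion
over a scanned angle range (±5°, step 0.05°). Two standard criteria were
rejected for cause: re-rotating the raster and scoring projection variance
aliases on desk-scale images (score peaks snap to angles whose total shear
is an integer pixel count, ~0.45° apart at 130 px width), and centroids of
*binarized* spots snap back toward the integer pixel lattice, hiding
sub-pixel rotations. The adopted criterion is resampling-free and graded:
every pixel darker than the image median votes with its darkness as
weight, and a candidate angle is scored by the magnitude of the weighted
phase sum of the counter-rotated coordinates at the spot-pitch frequency
(pitch measured from nearest-neighbour distances of detected spot
centroids). Injection-recovery lands within ±0.05° on all tested
geometries; the contract requires ±0.2°. A zero estimate skips resampling,
so unrotated images pass through bit-identically; a constant or gridless
image returns unchanged with a warning.

**Grid model.** Coordinates are 0-based, row-major, rectangles half-open.
Subgrids tile the membrane; within a subgrid each spot owns a
pitch × pitch target area; each antigen owns two spot positions. Layouts
serialize to JSON.

**Foreground clustering.** The pixels of one target area are split into
dark foreground and background by the two-cluster k-means objective on
their 1-D intensities, solved *exactly*: for sorted values the optimal
2-partition is a contiguous split, so all admissible splits are enumerated
with prefix sums and the global SSE minimum taken (first optimum on ties →
smaller foreground). This is deterministic, needs no initialization or
iteration cap, and provably coincides with the brute-force optimal
partition the tests check against. Zero-variance areas yield an empty
foreground and an "absent spot" flag.

**Area adjustment** (on by default, `--no-adjust` to disable). A spot that
overflows its target area is recaptured by growing the rectangle 1 px per
touched side per iteration, at most 5 iterations, re-clustering each time.
Two guards keep noise from corrupting the measurement: growth triggers
only when the *largest connected* foreground component crosses the border
with a chord of ≥ 2 px (single-pixel contacts are noise), and the final
foreground keeps only components anchored in the original area, so a
neighbouring spot swept into the enlarged rectangle is not counted.
Growth never lets the rectangle contain another spot's nominal centre;
a blocked side flags the spot for overlap. Without these guards, pixel
noise at sd 10 made half of all spots grow onto their neighbours and
destroyed depth recovery (correlation 0.52 vs ≥ 0.97 with them).

**Black top-hat.** Morphological closing with a square structuring element
minus the image (scipy's grey closing; reflective borders). The element
side defaults to the next odd integer ≥ 1.5× the layout's expected spot
diameter, so spots are narrower than the element and map to positive
peaks while the smooth background and features wider than the element map
to zero. The top-hat is applied to the full image; per-area application
would differ only at area borders.

**Intensities and profiles.** A spot's intensity is the mean of the
top-hat image over its foreground pixels (0 with a flag when the
foreground is empty). The two duplicates of an antigen are averaged and
rounded half-up to an integer in [0, 255]; a missing or empty replicate
leaves the remaining one (flagged), two missing give 0 (flagged).

Recovery under the model: noise-free, unrotated renders quantify to within
±1 intensity unit of the planted depths; at pixel noise sd 10 and 1° scan
rotation the Pearson correlation between recovered and planted depths
exceeds 0.95. Weak spots are slightly overestimated under noise (the dark
k-means cluster of a near-empty area is the dark tail of the noise), a
known small positive bias at the bottom of the scale that leaves ranks —
and hence the downstream AUC statistics — essentially intact.

## Normalization

Quantile normalization across sera: the reference distribution is the
column-wise mean of the sorted per-serum vectors; each serum's sorted
values are replaced by the reference. Tied values within a serum receive
the mean of the reference quantiles they span — integer grayscale profiles
are heavily tied, and splitting a tie would invent order not present in
the data. Consequences worth knowing:

- On tie-free data, normalization makes all rows share the reference
  multiset exactly and is exactly idempotent; with ties both statements
  hold up to the tie-averaging, which is how the property tests phrase
  them.
- Quantile normalization assumes most antigens are *not* differential.
  When a large fraction of antigens carries a strong one-sided group
  effect (≥ 10 % in our measurements), forcing all sera onto one
  distribution transfers part of that signal into null antigens and
  inflates their AUCs. At the default study conditions (5 % informative)
  the null false-flag rate of the informativeness rule stays below 5 %.
- A single-serum matrix is returned unchanged with a warning.

Inside cross validation the reference is always fitted on the training
fold only and applied to the held-out fold by rank — the held-out sera can
shift by any constant without changing either the training reference or
their own mapping (the leakage probe in the test suite).

## Antigen scoring

The per-antigen AUC is computed by an explicit threshold sweep over all
observed intensities (each threshold yields one sensitivity/1-specificity
point; trapezoidal area), which equals the midrank Mann–Whitney statistic
with ties counted ½ — the tests verify agreement to 1e-12 against an
independent rank-based oracle. Orientation: AUC > 0.5 ⇔ group 2 higher,
AUC < 0.5 ⇔ group 1 higher, and auc(g1, g2) = 1 − auc(g2, g1). An antigen
is *informative* when its AUC is strictly below 0.3 or strictly above 0.7;
the boundary values themselves are not informative. AUCs are computed on
normalized intensities; being rank-based, normalization matters only
through its tie handling.

## Classification protocol

Linear-kernel soft-margin SVM with cost C = 1 (scikit-learn's libsvm
solver — the protocol calls for a standard solver, not a bespoke one).
Evaluation: stratified k-fold cross validation (default 10 folds; reduced
to the smaller class size with a warning when a class is smaller),
repeated (default 10×) with freshly drawn folds per repetition.
Sensitivity, specificity and accuracy are computed per repetition from the
*pooled* fold confusion counts — stable with small classes — with group 1
of the task as positives. Summaries: medians across repetitions and 95 %
percentile intervals of the repetition values. Folds are assigned after
sorting sera by id, so results are exactly invariant to input row order.
Undefined metrics (zero denominator) are reported as missing rather than
0.

Per-serum decision scores are Platt-calibrated: a logistic model is fitted
on the training fold's SVM decision values and applied to the held-out
fold, giving each serum a probability of belonging to the task's group 2;
the mean across repetitions with threshold 0.5 supports a
probability-strip plot per serum.

**Permutation test.** Each of (default) 100 permutations reshuffles the
labels over the sera — class sizes are preserved, the stratified sense of
the test — and runs one full k-fold CV on the permuted labels. The
true-label repetition accuracies are compared against the permutation
accuracies with a one-sided Wilcoxon–Mann–Whitney test. With 10 true
values against 100 permutations the attainable p-value floor is ~1e-7
(normal approximation at complete separation); the reported p-value is the
computed one, never clamped to a smaller bound.

Chance levels: balanced classes give permutation accuracy centred on 50 %.
Imbalanced classes raise the floor — for class prior *p* a
label-independent classifier scores between p² + (1−p)² (random with the
prior; 53.4 % at 47 vs 80) and max(p, 1−p) (always-majority; 63 %).
Max-margin classifiers on permuted high-dimensional data land between
those poles; this pipeline measures a median near 58 % at 47 vs 80 with
1827 antigens.

**Randomness.** One top-level seed; repetitions, permutations and the
true-label CV derive child seeds through `numpy` seed sequences, so every
report and permutation distribution is bit-reproducible.

## Pipeline orchestration

`run_pipeline` chains simulate → (optional render + quantify) → normalize
→ auc → classify from a single `RunConfig` (JSON or YAML; unknown keys
rejected; flags override), writes TSV/JSON artifacts, and records a
manifest with a SHA-256 checksum per output plus all collected warnings.
A stage failure raises an error naming the stage; artifacts written so far
are renamed with a `.partial` suffix alongside a partial manifest.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
rendered test arrays are 30–60 antigens (130–150 px scans), statistical
tests use 50–500-antigen panels, and the two chance-level computations use
120 sera × 500 antigens and 127 sera × 1827 antigens with 100 permutations
each. These sizes exercise every code path of the full-scale pipeline; the
quantification stage scales linearly in spot count and the CV/permutation
stage in permutations × folds.

## Known limitations

- Spot detection assumes dark-on-bright polarity and roughly circular
  spots wholly inside (or within 5 px of) their target areas.
- The rotation estimator needs at least ~8 detectable spots and a
  reasonably uniform pitch; it corrects rotation only, not shear or
  nonlinear membrane distortion.
- Quantile normalization's null-preservation degrades when a large antigen
  fraction is strongly differential in one direction (see above).
- The per-serum score calibration is fitted on separable training folds in
  strong-signal regimes, where logistic calibration saturates; scores are
  then near 0/1 and should be read as rankings, not calibrated
  probabilities.
- Confidence intervals are percentile intervals over 10 repetition values
  and are correspondingly coarse.
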