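# seroarray

Autoantibody seroreactivity profiling from protein macroarrays.

Serum autoantibody repertoires shift in disease: sera from tumour patients
react with a partly different set of self-antigens than healthy sera.
Protein macroarrays — membranes spotted with thousands of bacterially
expressed proteins, each in duplicate — measure those repertoires: a
membrane is probed with one diluted serum, digitized on a flatbed scanner,
and each dark spot's intensity reports that serum's reactivity against one
antigen. `seroarray` implements the complete computational side of such a
screen for researchers analysing seroreactivity panels:

1. **Image quantification** — rotation correction, edge cropping, grid
   segmentation into spot target areas, per-spot k-means
   foreground/background pixel clustering, optional target-area adjustment
   for overflowing spots, black top-hat background removal with a square
   structuring element, and duplicate averaging into one integer profile
   per serum (one 0–255 value per antigen).
2. **Statistics** — quantile normalization across sera, and a per-antigen
   threshold-sweep ROC AUC separating two serum groups, with the
   *informative antigen* rule AUC < 0.3 or AUC > 0.7.
3. **Classification** — linear-kernel SVM (cost C = 1) evaluated by
   stratified 10-fold cross validation repeated 10 times (median
   sensitivity/specificity/accuracy with 95 % percentile intervals,
   quantile normalization refit inside every training fold), plus
   stratified label-permutation testing with a one-sided rank-sum p-value.
4. **Synthetic data** — a generator of array scans and profile matrices
   with known ground truth (planted informative antigens, per-serum scale
   factors, scan rotation, pixel noise), so every stage is testable
   without patient sera.

## The statistics in brief

For one antigen with normalized intensities in groups 1 and 2, every
observed value serves as a decision threshold *t*; sera above *t* count as
positive. Sweeping *t* traces a ROC curve whose area equals the midrank
Mann–Whitney statistic

  AUC = U / (n₁·n₂),  U computed with ties counted ½,

so AUC = 0.5 means indistinguishable distributions, 0 or 1 perfect
separation, AUC < 0.5 higher intensities in group 1, AUC > 0.5 higher in
group 2. Classification quality is reported as sensitivity TP/(TP+FN),
specificity TN/(TN+FP) and accuracy, pooled over the folds of each CV
repetition; chance level under label permutation for class prior *p* is
p² + (1−p)².

## Worked example

A synthetic screen with 400 antigens, 47 "case" vs 80 "control" sera, 5 %
of antigens shifted in cases by 25 intensity units (5× the profile noise):

```python
import seroarray as sa

cfg = sa.SimulationConfig(
    n_antigens=400, n_subgrid_rows=4, n_subgrid_cols=4, spots_per_subgrid=64,
    n_group1=47, n_group2=80, noise_sd=5.0, effect_size=25.0, seed=31)
matrix, truth = sa.simulate_profiles(cfg)

norm = sa.quantile_normalize(matrix)
table = sa.score_antigens(norm, *cfg.group_labels)
report = sa.cross_validate(matrix, cfg.group_labels, seed=31)
perm = sa.permutation_test(matrix, cfg.group_labels, n_permutations=100, seed=31)
```

prints (via the obvious `print` statements):

```
planted informative antigens: 20
antigens flagged informative: 36 of 400
median accuracy: 1.000  (95% CI 1.000-1.000)
median sensitivity: 1.000   median specificity: 1.000
median permutation accuracy: 0.535   p = 9.86e-08
```

All 20 planted antigens are flagged by the AUC rule (the extra flags are
borderline nulls dragged outside the band by normalization — see
`docs/methods.md`); the cross-validated SVM separates the groups
perfectly, while label permutation collapses accuracy to the 47-vs-80
class-prior chance level (~53 %), confirming the model is not overfitting.

The same pipeline runs from the shell:

```sh
seroarray simulate --seed 31 --n-antigens 400 --out-dir run/
seroarray auc      --profiles run/profiles.tsv --labels run/labels.tsv \
                   --task group1:group2 --out run/auc.tsv
seroarray classify --profiles run/profiles.tsv --labels run/labels.tsv \
                   --task group1:group2 --permutations 100 --seed 31 \
                   --out-dir run/clf
```

and `seroarray run --config config.json --out-dir run/` executes the whole
chain (optionally rendering and re-quantifying scan images) and writes a
manifest with a checksum for every output; identical config + seed gives
byte-identical artifacts.

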