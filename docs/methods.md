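# Methods

## Problem and model

A sample's taxonomic profile carries two kinds of geographic information:
a *shared gradient* (taxa whose abundance varies smoothly with latitude
and, more weakly, longitude) and *city signatures* (taxon shifts specific
to one city's surfaces, climate and transit system). The pipeline exploits
both, and the two evaluation designs deliberately separate them: city
signatures generalize only to cities present in training, the gradient
generalizes everywhere.

### Coordinate regression

Latitude and longitude are modeled jointly from standardized log2
abundance features with a multi-task Lasso:

    min_B  (1/2n) ||Y - XB||_F^2 + lambda * sum_j ||beta_j||_2,

where `beta_j` is the row of coefficients (latitude, longitude) of feature
j. The grouped L21 penalty makes feature selection shared across the two
responses. The path runs over 100 log-spaced lambdas from `lambda_max`
(the smallest lambda with an all-zero solution, computed from the row
norms of `X'Y/n`) down to `1e-3 * lambda_max`. Internal K-fold CV (default
10, folds stratified by city so every fold contains every city) scores
each lambda by the held-out squared error *summed over the two
coordinates*, and the **1-SE rule** picks the largest lambda whose CV
error is within one standard error of the minimum — deliberately
parsimonious. An ungrouped per-coordinate Lasso is available behind a
flag. Coordinates are treated as plain Euclidean responses: no longitude
wrap-around and no geodesic loss (a stated limitation; errors near the
date line are overestimated).

### City classification

L1-penalized multinomial logistic regression over cities, fit by
warm-started SAGA along a descending 20-lambda path, with per-sample
weights `w_i = 1 - n_city(i)/N` to damp city-size imbalance (weights are
not renormalized; this only rescales the effective lambda). Lambda is
chosen by the same 1-SE rule on held-out *weighted multinomial deviance*.
The penalty is ungrouped across classes. Argmax ties break toward the
first city in sorted order. Classification is bridged to coordinates by
assigning the predicted city's panel coordinates, which makes its MSE
directly comparable to the regression's. When every feature is constant
the optimizer is bypassed and the analytic intercept-only solution
(weighted class priors) is returned — SAGA's step size degenerates on
all-constant designs.

A random forest with per-class down-sampling is provided as a nonlinear
baseline: each tree trains on a bootstrap in which every class is
resampled to the minority class size; out-of-bag votes give an internal
accuracy estimate. It is built from individual decision trees because
standard forest implementations do not expose balanced per-tree bootstraps
with OOB retention.

### Evaluation designs

* **Nested K-fold CV** (default 10 outer folds, stratified by city, folds
  reduced with a warning if the smallest city is smaller than the fold
  count): per fold, the feature scaler and the model (with its own
  internal lambda CV) are fit on the training portion only; every sample
  is predicted exactly once. This measures performance on *pre-trained*
  origins.
* **Leave-one-city-out (L1CO) CV**: all samples of one city are held out
  together. This measures performance on *new* origins; for a classifier
  the confusion diagonal is structurally zero.

Scores: MSE per coordinate in squared degrees with the total as their sum;
r² as the *squared Pearson correlation* between predicted and true values
(not 1 − SS_res/SS_tot — the two differ for biased predictors, and the
correlation form matches how prediction scatterplots are usually
annotated); r² of a constant predictor is reported as 0 with a warning.
Model comparison per city uses the one-sided Wilcoxon rank-sum on total
squared errors (exact null distribution below n = 50 per group),
Benjamini–Hochberg adjusted across cities.

### New-origin flag

The Simpson index `s = 1 - sum_k p_k^2` of a sample's class-probability
vector measures prediction ambiguity (0 = confident one-hot, 1 − 1/K =
uniform). Running the classifier through both CV designs yields two
ambiguity values per training sample — nested CV mimics a pre-trained
origin, L1CO mimics a new origin. A Bayes classifier with one Gaussian
KDE per setting (Silverman's rule-of-thumb bandwidth
`0.9 min(sd, IQR/1.34) n^{-1/5}` per class, epsilon fallback of 1e-3 for
zero-variance groups) converts an ambiguity value into a posterior
probability of "new origin"; the decision threshold is 0.5 posterior, and
an ROC over all thresholds is exposed. Priors default to the empirical
record frequencies (≈ 1/2 by construction) and can be forced equal.
Posteriors are computed in log space so queries far outside both supports
do not underflow. Simpson values are clipped to [0, 1] before density
estimation; no boundary reflection is applied (a documented
simplification — densities leak mass slightly past 0 and 1). Evaluation is
leave-one-out: each record is classified by a model refit without it.

LOO on null data (both settings drawn from one distribution) comes out
*below* 0.5, not at it: removing a record depresses its own class's
density at that point. This pessimistic bias is expected and harmless —
the flag is only trusted when the two distributions actually separate.

## Normalization choices

* CSS quantile: taken over each sample's **positive** counts with linear
  interpolation; counts **equal** to the quantile are included in the
  scaling sum. These dialect choices are fixed here for reproducibility
  since the CSS definition leaves them open.
* `scale_constant` = 1000. Any positive constant only shifts the log2
  intercept.
* log2 pseudocount = 1, so zero counts stay zero before standardization.
* Zero-variance features are dropped when the scaler is fit (training
  data) and never at predict time; applying a scaler to data lacking one
  of its features is an error.
* Filtering rule: a taxon is kept iff strictly more than
  `min_samples_exceed` samples contain at least `min_reads` reads
  (defaults 100 reads; the "more than" boundary is deliberate).
* PCoA uses the Cailliez correction: the smallest constant c added to all
  off-diagonal dissimilarities that removes negative eigenvalues, computed
  as the largest real eigenvalue of the 2n x 2n companion block matrix.
  After correction, distances reconstructed from all retained axes match
  the corrected dissimilarities.

## Synthetic data generator

The generator emulates a multi-city swab survey: a training panel
(default 15 cities x 18 samples) and a disjoint mystery panel (8 cities),
with latitudes drawn in [-55, 65] (the inhabited band), longitudes over
the full circle, and continents assigned as six longitude-thirds x
hemisphere blocks. For taxon t in city c the expected log2 intensity is

    mu_tc = baseline_t + b_lat,t * lat_c + b_lon,t * lon_c + e_tc,

with `e_tc ~ N(0, city_effect_sd)` drawn once per (taxon, city) from a
city-keyed stream (so the same city always gets the same signature under a
given seed). Intensities are closed to a library size drawn uniformly from
50k–150k and counts are negative binomial with dispersion 0.5
(overdispersed shotgun-like counts); independent zero inflation
(default 0.1) is applied before closure, so dropped taxa free reads for
the rest. 200 species nest into 60 genera and 25 families by a random
fixed mapping under the seed; coarser tables are exact column sums.
Defaults: 10 informative taxa with latitude slopes of +/-0.05 log2 units
per degree and longitude slopes of +/-0.02 (halved because the longitude
range is twice as wide), city_effect_sd 0.5.

The optional protocol-batch city (single-end, 125 bp) receives a fixed
log2 shift (`batch_shift`, default 2.0) on a seed-determined random half
of taxa before sampling — a systematic protocol artifact. When protocol
heterogeneity is enabled, the last city of *each* panel is single-end,
since real multi-center studies have protocol variation on both sides of
the train/test split.

What the generator does **not** emulate: phylogenetic covariance between
taxa, seasonality, surface types, within-city micro-environments, read
level artifacts (misassignment, contamination), or real taxon names.
Passing tests therefore demonstrate that the pipeline recovers planted
signal of the stated form under overdispersed compositional noise — not
that real urban microbiomes carry signal of that strength.

## Study conditions used by tests and the acceptance script

Simulation-heavy checks run at reduced sizes chosen to keep the full suite
fast while leaving each property's outcome unambiguous:

* Signal recovery: the full 15 x 18 world, 20 seeds.
* CV-design properties (L1CO vs nested error): 8 cities x 10 samples,
  120 species, 30-lambda paths, 20 seeds.
* Ambiguity and novelty: 6–8 cities, `city_effect_sd = 1.5`. The flag's
  designed regime is *confident* classification of pre-trained origins
  (nested accuracy ~0.94 at these settings); with weak signatures
  (sd 0.5) heavily penalized classifiers emit near-uniform probabilities
  in both CV settings and the ambiguity contrast collapses — the flag is
  not meaningful there, and the stronger setting mirrors the high
  pre-trained accuracy regime the method targets.
* Protocol mixing: 15 paired-end cities vs the same plus one single-end
  batch city, clean mystery panel, regression model. In this generator
  family the inclusion of one corrupt city degrades mystery predictions
  only mildly on average (median MSE ratio ~1.01 at the default shift,
  ~1.2 at extreme shifts): per-fold z-scoring absorbs the shifted city —
  its artifact features act as a benign city indicator — and the Lasso is
  robust to ~6% corrupt training rows. A protocol artifact that merely
  shifts half the taxa of one city is therefore *not* sufficient to
  reproduce the several-fold error inflation seen when real heterogeneous
  protocols (which corrupt read-level taxonomic assignment globally) are
  mixed; the corresponding acceptance test documents this gap and is
  expected to fail.

## Numerical notes

* SAGA logistic fits use tol 1e-3 and 300 iterations per warm-started
  path step; coefficients at matched penalties agree with tightly
  converged fits to ~1e-4, adequate for lambda selection. Tests that
  assert exact invariances pass tol 1e-8 explicitly.
* The multi-task coordinate-descent path uses tol 1e-6 (1e-12 when a
  fixed lambda is requested, so near-zero penalties reproduce OLS).
* All stochastic components (world generation, counts, fold assignment,
  SAGA, forest bootstraps) are driven by explicit seeds; generators are
  bit-reproducible under a fixed seed.
* Bray–Curtis between two all-zero samples is undefined and raises; a
  single all-zero sample is at distance 1 from everything.
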