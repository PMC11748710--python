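# Methods

## The grading problem

Nuclear cataract severity is graded on a three-level ordinal scale —
normal (code 1), mild (2), severe (3) — from anterior-segment OCT. All
computation happens inside the nucleus region, supplied as a binary mask
per image; segmentation itself is out of scope. The working object is the
nucleus's discretized intensity distribution: opacity shifts histogram
mass upward and fattens the bright tail, while the raw images remain
visually similar across grades.

## Histogram model

Pixels with intensity in `[range_lo, range_hi]` (inclusive) are binned
into `N = ceil((range_hi − range_lo)/interval)` intervals with left
boundaries `L_i = range_lo + (i−1)·interval`, `i = 1..N`. Conventions the
definitions do not pin down, fixed here:

* **Edges.** Bins are half-open `[L_i, L_i + interval)`; the last bin is
  closed at `range_hi`, so the upper boundary value is counted exactly
  once. When the span is not a multiple of the width the last bin is
  simply narrower.
* **Normalization.** Out-of-range pixels are excluded from both the
  numerator and the denominator of `X_i`, so the retained mass sums
  to 1. Rationale: the default 5–150 window exists to *remove* the
  near-zero background mass; leaving it in the denominator would let the
  excluded mass distort every proportion. A config flag
  (`normalize_in_range_only=False`) switches to the all-pixel
  denominator; percentile thresholds then scale with the retained total
  mass so they remain well defined.
* **Bit depth.** Only 8-bit single-channel images are accepted; anything
  else is rejected with an error, never silently rescaled.

Defaults: range 5–150, interval 5 (N = 29). The alternatives 0–255 and
interval 10 are first-class settings exercised by the ablation command.

## Feature catalog

The 23 histogram features operate on bin **indices** `i` where the
formula says so (all moment-type quantities: D-Mean `μ = Σ i·X_i`,
D-Variance, D-Skewness, excess D-Kurtosis, the absolute deviations,
entropy, uniformity, percentile indices, mode index, gradient locations)
and on bin **boundaries** `L_i` for the intensity-unit quantities
(D-Minimum/Maximum, D-Interquartile, D-Range, IHC-Dispersion). The mixed
catalog is deliberate; units are part of each feature's identity.

Fixed conventions:

* Percentile indices (D-Median, D-Ten, D-Ninety, and the quartile
  boundaries) are the *smallest* index whose cumulative proportion
  reaches the target.
* D-Minimum/D-Maximum are the boundaries of the lowest/highest **occupied**
  bin (`X_i > 0`). On a full-range histogram the zero bin is practically
  always occupied, which is why D-Minimum carries no information there.
* IHR-Mean sums `|i−μ|·X_i` over the bins between the 10th and 90th
  percentile indices **without renormalizing** the truncated mass — the
  literal reading of its definition; `renormalize_ihr=True` gives the
  renormalized variant.
* IH-Mode is the **index** of the histogram peak (first maximum on
  ties), keeping its unit consistent with the other location features.
* Gradients are forward differences `g_i = X_{i+1} − X_i`; ties in
  argmax/argmin resolve to the smallest index.
* Degenerate 0/0 statistics return 0 with a debug-log note: skewness and
  kurtosis of a single-occupied-bin histogram, and IHC-Dispersion when
  `L_75 + L_25 = 0` (possible only on windows starting at negative or
  zero boundaries).
* I-STD uses the population denominator `n` (config-switchable to
  `n − 1`); the intensity features see **all** masked pixels, unfiltered.

## Retraining Shapley values

`φ_i` weights the change in model output caused by adding feature `i` to
every subset `S` of the remaining features, each model **fully
retrained** on its subset. Choices left open by the formula:

* **Model output.** `f_S` returns the predicted class probability;
  values are computed per class, so the result is a
  `(samples × features × classes)` array. Probabilities make `φ`
  continuous in the model parameters (a hard class decision would not
  be).
* **Empty set.** `f_∅` predicts the training-label class frequencies.
* **Exact vs sampled.** Exact enumeration costs `2^|T|` retrainings and
  is refused above 12 features. The sampled estimator averages marginal
  contributions along random feature orderings — an unbiased estimate of
  the same weighted sum — drawn as antithetic (permutation, reverse)
  pairs to cancel order-position variance; the seed is mandatory.
  Subset predictions are memoized (bounded by memory, ~200 MB), which
  makes sampling at small `|T|` nearly free because only `2^|T|`
  distinct subsets exist.
* Evaluation uses the same rows the models are trained on, matching how
  the importance analysis is run on a training cohort.

Exactness is enforced by the three axioms in the test suite: efficiency
(`Σ_i φ_i = f_T − f_∅` per sample and class), symmetry (duplicated
columns get equal values), and the null axiom (a feature that never
changes a prediction gets 0).

## Pearson correlation and selection

PCC is computed from sums (covariance over the product of standard
deviations); a constant input yields 0 by convention, and the
correlation-matrix diagonal is likewise 0 for constant features —
mirroring how a constant D-Minimum column behaves on full-range
histograms.

Selection is a two-stage rule: drop features with overall mean-|φ| below
`shap_floor` (default 0.015), then resolve redundant pairs — any pair
with `|PCC| ≥ redundancy_threshold` (default 0.9) plus explicitly listed
pairs — by dropping the lower-Shapley member. On an exact tie the
non-index-valued member goes (the raw-statistic partner of a location
feature), else the alphabetically later name. Canonical feature order is
preserved. Applied to the shipped clinical importance table with the
three documented pairs (G-Maximum/GI-Maximum, G-Minimum/GI-Minimum,
D-Median/I-Median), the rule retains 22 of 27 features; the
G-Minimum/GI-Minimum case is a true 0.164/0.164 tie resolved by the
tie-break.

## EMRR

One ridge regression per grade on one-vs-all 0/1 targets, closed form
`ŵ_c = (XᵀX + λI)⁻¹XᵀY_c` solved as a symmetric positive-definite linear
system (never an explicit inverse). Parameters:

* `λ` (default **1.0**, exposed everywhere): the training objective does
  not fix it; 1.0 is a conventional midpoint for z-scored features.
* **Intercept penalization** (default on): the objective penalizes the
  full augmented weight vector including `ω_0`, and the implementation is
  literal about it; `penalize_intercept=False` gives the conventional
  free-intercept variant.
* **Standardization** (default on): columns are z-scored with training
  statistics stored in the model. Ridge shrinkage is scale-sensitive and
  the 27 features span bin indices, proportions, bits and raw
  intensities; without standardization λ would act on arbitrary units.

Scores combine by softmax (max-subtracted) and argmax; ties go to the
lowest grade code. Softmax is monotone, so decisions from scores and
probabilities coincide.

**Masking.** A known property of one-vs-all linear regression inherited
by this classifier: when the class means are collinear in feature space
(e.g. a single feature that increases linearly with grade, balanced
classes), the middle class's fitted indicator line is dominated and the
middle grade is never predicted — a perfectly grade-aligned single
feature then caps at 2/3 accuracy. A middle-heavy class balance or
non-collinear multi-feature geometry removes the effect; real
histogram features are non-linear in grade, which is why per-feature
accuracies above the majority rate are attainable. The test suite pins
both regimes.

## Metrics

Each class is scored one-vs-rest (TP/FN/FP/TN from the count matrix);
ACC, PRE, SEN, SPE, F1 per class, macro = unweighted mean. Zero
denominators yield 0 with a flag. The **plain (micro) accuracy** —
trace over total — is reported alongside because for three or more
classes it differs from both the macro and the pooled one-vs-rest ACC
(the three coincide only in the binary case, which is the identity the
suite checks). Chance-level and per-feature accuracies are micro
accuracies: that is the convention under which a constant feature scores
the majority-class rate and balanced chance is 1/3.

## Synthetic cohorts

Each grade's nucleus pixels are drawn from a three-part mixture:
a background spike (uniform integers 0–4), a truncated normal
"opacity" component on [0, 255] (rounded), and a bright tail (uniform
150–255). Defaults:

| grade  | background wt | opacity mean | opacity sd | tail wt |
|--------|---------------|--------------|------------|---------|
| normal | 0.30          | 30           | 8          | 0.00    |
| mild   | 0.20          | 55           | 12         | 0.05    |
| severe | 0.10          | 85           | 18         | 0.15    |

Opacity mean/sd/tail encode the upward shift and tail growth with
severity; background weight falls with severity because an opaque
nucleus leaves fewer near-zero pixels. Images are 72×96 with a 24×34
semi-axis elliptical nucleus (~2,500 pixels) unless configured
otherwise; pixels outside the ellipse are zero. Image `k` of a dataset
uses derived seed `seed + k`, so any subset regenerates independently
and the whole dataset is a pure function of its configuration. The exact
per-value pmf of the mixture is available analytically
(`pixel_value_pmf`) and serves as the oracle for sample-mean and
divergence checks.

What the generator does **not** emulate: speckle statistics, anterior
anatomy, layered lens structure, segmentation error, intra-grade
clinical heterogeneity. Passing tests therefore demonstrate that the
pipeline machinery is correct and that histogram-separable classes are
recovered — not that clinical-grade accuracy transfers to real AS-OCT
data.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen to
keep sampling error well inside the asserted bands: 200 images/class for
the separable-recovery check (held-out accuracy ≥ 0.95), 1,000/class for
the collapsed-profile chance check (band 1/3 ± 0.04; SE ≈ 1.6% at 900
test images), 8-feature problems for exact-vs-sampled Shapley (2,000
permutations), and 100 random pixel lists for the brute-force feature
oracle. The acceptance script uses 150/class (separable) and 300/class
(collapsed), which keeps its chance estimate within ±3 SE ≈ ±8.5% of
33.3%.

## Known limitations

* The importance analysis retrains `O(2^|T|)` or
  `O(n_permutations·|T|)` models; it is practical because each ridge fit
  is closed-form, but a different `model_factory` may make sampled mode
  slow.
* The selection rule reproduces the clinical subset only given the
  published importance values; recomputed Shapley values on synthetic
  cohorts yield cohort-specific (and equally valid) selections.
* Ordinality of the grades is used only through the PCC-vs-label view
  and tie-breaking; the classifier itself is nominal one-vs-all.
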