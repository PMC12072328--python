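# Methods

## Problem and pipeline

The package estimates a child's weight from a single photograph-derived
pose plus demographic metadata, for ages 1–155 months. The estimation path
is deliberately two-stage: the network predicts *height*, and weight is
derived through a growth reference conditioned on a visually assessed
habitus band. Height is the quantity a pose actually constrains; weight
enters only through population structure. A direct weight-regression mode
(`ModelConfig(target="weight_kg")`) is retained for comparison, since
either target is defensible for this architecture.

## Growth reference

Each (sex, age-month) cell carries a median and coefficient of variation
for height and weight; within a cell the distribution is log-normal,
q(p) = median·exp(z_p·σ) with σ = √ln(1+cv²). This is the LMS family in
its L→0 limit: strictly positive, right-skewed, and percentile curves
cannot cross while the median curve is monotone. The packaged reference is
synthetic, built from smooth parametric curves:

* median stature h(a) = 49 + 28.3·(1 − e^(−a/10)) + 0.519·a cm (fast
  saturating infant growth plus a linear childhood phase; ~75 cm at 12
  months, ~108 cm at 5 years, ~152 cm at 12 years), ±0.5% by sex;
* median weight couples allometrically, w(a) = 4.3·(h(a)/h(1))^2.1 kg
  (~8.6 kg at 9 months, ~15 kg at 3 years, ~40 kg at 12 years);
* height CV 0.035; weight CV rises linearly from 0.11 at 1 month to 0.20
  at 12 years, mirroring how real references widen through childhood. The
  slope is small enough that weight quantiles remain strictly increasing
  in age for every percentile in (0.02, 0.98), which the tests assert.

Real chart tables can be dropped in via the same CSV schema
(`sex, age_months, height_median_cm, height_cv, weight_median_kg,
weight_cv`); everything downstream is table-agnostic.

Habitus bands anchor to weight-for-age: thin < P25, overweight > P75,
boundaries inclusive to normal (the clinical definitions are strict
inequalities on the outer bands). A band collapses to a single displayed
weight at its representative percentile — 12.5 / 50 / 87.5 by default, the
band midpoints; the mapping is a parameter because no single convention is
canonical. `height_to_age_equivalent` inverts the median-height curve by
linear interpolation between grid months; it exists purely to bridge the
regressor's continuous height output to the age-indexed chart.

## Synthetic cohorts and capture

`sample_cohort` draws ages per stratum (1–12, 13–71, 72–155 months) with
the default mix 150:825:360/1335, uniform within a stratum; sex is
Bernoulli(0.5). A latent habitus percentile ~ U(0.02, 0.98) sets height;
weight comes from a Gaussian-copula-correlated percentile (ρ = 0.7), so
tall children tend to be heavy but imperfectly. The assessed habitus is
the chart classification of the sampled weight, flipped to an adjacent
band with probability 0.2 — visual habitus assessment after brief training
is known to be error-prone, and 10–30% misclassification is a realistic
regime.

`render_pose` places the 17 keypoints from body-segment proportions of
stature. The vertical chain (head, trunk, thigh, shank) sums to exactly 1,
so the pre-noise head-to-heel pixel span equals stature × scale; the crown
is collapsed onto the nose landmark, and eyes/ears sit just below it as
off-chain decoration. The head fraction shrinks from 1/4 of stature at 1
month to 1/7 at 12 years, linear in log-age — the age-correlated shape
signal that makes pose informative about body size. Corruption model, in
order:

| parameter | default | rationale |
| --- | --- | --- |
| `proportion_sd` | 0.04 | per-subject segment-proportion spread; children of equal age and stature differ in build (sitting-height ratio SD is a few % of stature) |
| `pixels_per_cm` | 5 | tablet camera at ~1 m on a 768×1024 frame |
| `scale_jitter_sd` | 0.15 | log-normal monocular scale ambiguity: handheld capture distance is not fixed and no reference object is used |
| `rotation_sd` | 5° | camera tilt about the figure centroid |
| `translation_sd` | 10 px | framing offset from image center |
| `landmark_noise_sd` | 10 px (≈2 cm) | realistic pose-detector localization error on clothed, imperfectly positioned children |

Keypoints pushed off the image are clamped back and flagged at confidence
0.1. `CaptureConfig.noiseless()` zeroes every noise scale, making capture a
deterministic projection — the basis of the parameter-recovery tests.

These defaults were set in one calibration pass so that the default
synthetic study reproduces the error regime of clinical photographic
weight estimation (end-to-end weight MAPE around 8–10%, against ~12%
reported clinically for such systems); with cleaner optics the synthetic
task is unrealistically easy, because age alone pins height to ~2.8% MAPE.
What the generator does **not** emulate: real limb articulation and
occlusion, clothing, non-supine postures, pose-detector failure modes
(swapped left/right, missed detections), or real growth-chart skewness
(L ≠ 0). Passing recovery tests therefore demonstrate that the pipeline's
inference machinery is correct and well-conditioned under a plausible
noise budget — not that clinical accuracy would match.

## Features

Distances use normalized coordinates (x/width, y/height, clamped to
[0, 1]); normalization is idempotent, detecting already-normalized input.
Consequences, stated rather than hidden: translation invariance holds
exactly; rotation invariance holds only for square images (anisotropic
normalization otherwise); absolute scale is partially lost, so the network
must infer size from proportions plus metadata. Metadata encoding: sex
male=0/female=1, age divided by 155 (the maximum enrollable month), habitus
one-hot — bounded, dimensionless inputs sized for a small network. The
16-edge skeleton is the canonical connectivity for these 17 landmarks and
is configurable.

## Regressor

The network and optimizer are implemented directly in numpy: He-normal
initialization (std √(2/fan_in)), inverted dropout on both hidden layers
during training only, Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁸), MSE loss,
mini-batches of 16, ≤200 epochs, early stopping on validation loss with
patience 20 (~10% of the epoch budget) and best-epoch weight restore. The
80:20 split uses floor(0.8·n) training cases — 278 records split 222/56 —
shuffled by seed, unstratified. All randomness (split, init, batch order,
dropout masks) derives from the config seed, so training is bit-for-bit
reproducible on a fixed platform.

Numerical choices: inputs and targets are z-scored with training-set
statistics stored in the checkpoint and inverted at prediction; on raw
centimeter scales Adam's ~10⁻³-per-step updates cannot traverse the
~100-unit output offset inside the epoch budget. A non-finite loss aborts
training with the epoch index rather than propagating NaNs. Degenerate
constant targets are handled by a σ ≥ 10⁻⁸ guard, making the prediction
exactly the constant. Checkpoints are portable JSON carrying the config
echo, scaling, weights and the feature column order, which is verified at
load.

At estimation time a predicted height outside the chart's median-height
range raises a range error with the raw prediction attached; pipeline
callers (CLI evaluate, experiments) opt into clamping to the curve
endpoint instead, so one noisy outlier does not abort a cohort run.

## Length-zone baseline

Interval lookup via binary search over zone lower bounds; zones are
validated as contiguous, sorted, spanning exactly [45.9, 146.5] cm with
non-decreasing weights; the final zone is upper-inclusive. The packaged
table is synthetic — 23 zones whose weights follow the package's own
allometric weight-for-length curve — because printed commercial tape
values are replaceable data, not algorithmic content. Lengths off the tape
raise an error; the evaluator counts such children in an exclusions block.

## Agreement statistics

Percentage errors are signed, predicted − actual, over actual. The
Bland–Altman difference direction is likewise predicted − actual. The LOA
standard deviation uses the population convention (÷n) by default, under
which rmse² = mean_diff² + sd² is an exact identity — this is what lets an
RMSE be reconstructed from printed limits of agreement; the sample
convention is available as an option. PW thresholds are inclusive
(|e| ≤ 10 counts as within 10%). ICC is ICC(A,1) — two-way random,
absolute agreement, single measures, the conventional form for
method-vs-reference interchangeability — computed from the two-way ANOVA
mean squares, with the Satterthwaite/F confidence interval and an
F = MSR/MSE test of ICC = 0; the tests cross-check value, p and CI against
an independent implementation and a brute-force ANOVA oracle. Age
subgroups are [1, 12], [13, 71], [72, 155] months: the conventional labels
("1–12 months", "2–5 years") leave 13–23-month-olds unassigned, and they
are placed in the middle group so the partition is exhaustive. Cohort
summaries report median [IQR] (linear-interpolation quantiles) for
continuous variables and n (%) at one decimal (round-half-to-even) for
categories. The two-proportion sample-size operation implements the
standard normal-approximation formula (pooled under H₀), ceiled; for 60%
vs 70% at α = 0.05 and power 0.8 it gives 356 per group, confirmed by
exact binomial power enumeration.

## Problem sizes

Recovery experiments run at n = 1000 subjects; the property batteries use
1000 random datasets (metrics), 20 fixtures (ICC), and 1000 lookups
(zones). These sizes give stable estimates — the noisy-capture weight MAPE
varies by well under one percentage point across seeds — while keeping the
full suite and the acceptance script each under a minute on one CPU.

## Known limitations

* The stick-figure renderer is geometric, not photometric; no pose
  detector is ever run, and detector-specific failure modes are out of
  scope.
* The synthetic growth reference is smooth and log-normal; real references
  carry estimation noise and skewness parameters.
* The habitus→percentile collapse discards within-band information by
  construction; the direct weight-target mode sidesteps it but discards
  the growth reference instead.
* Infant (1–12 month) accuracy is structurally weaker at small training
  sizes because infants are ~11% of the default age mix.
* Continuous retraining from newly captured data is not implemented; the
  model is train-once.
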