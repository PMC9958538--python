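# Methods

This note documents the models and procedures implemented in `scrivo`, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions.

## 1. Screening model

The analysis predicts a binary *at-risk-of-dysgraphia* label for each child
from three feature families recorded during a gamified visual-perception
battery (six games × three difficulties):

* **game**: completion time for every level, error counts for the
  option/search games;
* **eye**: seven metrics from the most *challenging* levels (chosen by
  across-subject variance of completion time, errors variance as tiebreak):
  numbers of gaze positions and fixations, mean fixation duration,
  per-panel gaze fractions, gaze- and fixation-based indecision, and
  Standard Distance dispersion;
* **drawing**: per copying/tracing level, tract counts, discontinuity
  length, fraction of discontinuous tract onsets, inked length, centroid
  position, distance from the cohort center, dispersions from centroid and
  start, completion time, and (tracing only) out-of-trace length and point
  fraction.

The label comes from the BVSCO-2 handwriting-speed battery: each of three
one-minute exercises yields a graphemes-per-minute count; exercise *e* of a
grade-*g* child is under threshold when
`count < mean(g, e) − 2 · sd(g, e)` (strict; equality is over threshold),
and the child is at risk when under threshold in **at least one** exercise.
The real normative table is copyrighted, so the package ships a synthetic
default (means 30/40/50 graphemes per minute for grades 1–3, SD 8, same for
all three exercises — plausible ordering, not published values) and reads a
user-supplied `norms.csv` otherwise.

## 2. Eye-tracking pipeline

* **Cleaning.** Gaze and fixation streams are filtered at confidence
  ≥ 0.70. The threshold is *inclusive*: the cutoff is a minimum, so a
  sample exactly at 0.70 is retained.
* **Screen partitioning.** For the four-panel games, K-means with k=2 on
  the x coordinate splits the screen into two horizontal clusters (the
  smaller-mean-x cluster is the left/reference panel); K-means with k=3 on
  the y coordinate of the right cluster yields the three option panels,
  ordered top→bottom by decreasing mean y. Both stages use 10 restarts and
  a fixed seed, so the partition is deterministic. Fitting on each child's
  own samples absorbs the session-specific offset between the head-mounted
  tracker and the tablet. Fixations are assigned to the partition fitted on
  the gaze samples (one geometry per level, never refitted).
* **Indecision.** A bounce is a transition between consecutive events whose
  panel roles differ *and* one of the two is the target; option↔option
  transitions are not bounces. Counted separately over the gaze-sample
  sequence and the time-ordered fixation sequence.
* **Dispersion.** Standard Distance in its population (1/n) form.
* **Gaze fractions** use gaze positions (not fixations).
* **Per-grade scaling** is a plain z-score within grade (population SD;
  singleton or zero-spread groups scale to 0). By default only the
  eye-tracking metrics are scaled — they are the features most affected by
  grade-dependent session behavior — with `scaling_scope: all` available.
* A level whose cleaned sample stream is empty (or whose partition is
  degenerate) yields missing values; subjects with any missing value are
  excluded from every predictor set, so all sets share one cohort.

## 3. Drawing pipeline

* **Tracts.** A tract is a pen-down segment. Raw point streams are split at
  explicit pen-lift events and at inter-point time gaps above 100 ms (the
  tablet samples at tens of Hz, so a 100 ms silence implies a lift).
* **Discontinuity.** `discontinuity_length` sums the Euclidean gap between
  the last point of each tract and the first point of the next.
  `tract_discont_perc = (n_tracts − 1) / n_tracts` — the fraction of tract
  onsets that follow a discontinuity. No canonical formula exists for this
  descriptor; this definition is bounded in [0, 1) and strictly monotone in
  the number of pen lifts, which is what a screening feature needs.
* **Dispersions** are means of point distances (from the centroid, from the
  first point), not RMS — "dispersion from a point" is read as an average
  distance; the test oracles pin this convention.
* **Out-of-trace length** counts only segments with *both* endpoints out of
  trace; boundary-crossing segments are ambiguous and excluded
  (conservative under-count).
* **Cohort center.** `distance_from_center` measures each centroid against
  the mean centroid of the analyzed cohort for that level. The default uses
  the full cohort, which leaks a little cohort information across CV folds;
  `cohort_center_mode: train` recomputes the centers from the training fold
  inside the nested CV for a leak-free variant. The default mirrors the
  usual practice of computing spatial norms once per dataset.

## 4. Classification

* **Baselines.** Gaussian naive Bayes, random forest, SVM, and
  gradient-boosted trees, each at its default settings, over six repeated
  stratified 80/20 splits (mean ± SD of train/test accuracy). The
  boosted-tree default is deliberately low-regularization
  (`min_child_samples=2`, 200 iterations): boosted-tree libraries tuned for
  larger data memorize small cohorts, and the baseline table is meant to
  exhibit exactly that train≈1.0 / test-drop overfitting signature.
* **Nested CV.** Stratified 5-fold outer loop; per outer fold, a 3-fold
  inner grid search on the outer-train portion only, over tree depth
  {3, 5} × iterations {100, 300} × learning rate {0.05, 0.1} (a deliberately
  tiny grid — deterministic and desk-scale). Outer-test data never touch
  fitting or selection.
* **"Train" metrics.** Reported train metrics are the selected
  configuration's *inner out-of-fold* metrics on the outer-train portion —
  a cross-validated estimate — rather than predictions of the refit model
  on its own training data. A boosted tree refit on ~40 subjects predicts
  its training data almost perfectly, so refit-on-train metrics would be a
  constant 1.0 and carry no information; the cross-validated estimate is
  comparable to the test metrics and makes the train/test gap meaningful
  ("performance steady across validation and test" is the behavior nested
  CV is used to demonstrate). Splits are stratified by label to protect the
  minority class. Precision/recall/F1 are computed per fold and then
  averaged (mean ± SD over the five folds); recall is always reported,
  since missing an at-risk child costs more than a false alarm.
* **Shapley values** are computed with the exact tree-path-dependent
  algorithm native to the boosted-tree library (`pred_contrib`), so the
  per-subject attributions plus the base value reproduce the raw log-odds
  output to machine precision. Features are ranked by mean |Shapley value|;
  optional top-k selection runs *inside each outer-train fold* by default
  (no selection leakage), with a `selection_mode: global` switch for the
  simpler select-once variant.

## 5. Synthetic cohort generator

Study datasets in this domain are private, so the generator provides the
statistical structure the analysis assumes:

* A latent handwriting-ability factor `a ~ N(0, 1)` per child (grades
  sampled with probabilities 15/53, 22/53, 16/53, mirroring a typical
  first-to-third-grade cohort). Conditional on ability, every feature
  family has mean shifted by `effect_size[family] · a` plus independent
  noise — features are conditionally independent given ability. An optional
  `modality_sd` knob adds a shared per-modality nuisance factor
  (test-retest style) for robustness studies; it is **zero by default**, as
  the conditional-independence contract requires.
* Defaults (units per ability SD): game time −3.0 s (noise 3.0 s, scaled up
  with difficulty), errors −0.4 (noise 0.45), gaze-bounce logit −0.8 around
  a base switch probability 0.35, return-to-target logit +0.5 around 0.55,
  log fixation duration −0.12 around 280 ms (lognormal, σ=0.35), drawing
  log-scale +0.08, placement offset +0.04 screen units (at-risk children
  draw smaller and to the lower left), log pen-lift rate −0.4 around 2
  lifts per drawing, copying time +2.5 s (stronger children take *longer*
  to copy), tracing log-tremor −0.3, and BVSCO-2 +24 graphemes/min with
  residual SD 8. The BVSCO coupling is strong because the under-threshold
  rule must flag a realistic share of a school cohort (roughly 35–45% at
  risk with these defaults, as screening studies report), which requires
  the cohort's count dispersion to be much wider than the normative SD.
* Level *salience* weights (0.3–1.2) make the harder masked-form-constancy,
  visual-closure and figure-ground levels much more discriminative than the
  easy ones, so variance-based challenge selection has something real to
  find.
* **Gaze streams** are renewal processes of fixations at panel centers
  (Gaussian placement scatter 0.03, within-fixation sample jitter 0.015,
  200 Hz sampling). The panel-visit sequence is a Markov chain: at each
  fixation the gaze switches panel with probability `p(a)`; from an option
  it returns to the target with probability `q(a)`. The generator records
  the ground-truth target↔option transition count, and the analytic
  expectation of the lumped two-state chain is used as a test oracle. A
  spec-controlled fraction of confidences (default 12%) falls below the
  0.70 cleaning threshold.
* **Drawings** are the level templates scaled/translated by ability,
  sampled at 60 Hz along the path with smoothed (temporally correlated)
  tremor — white noise would inflate arc-length features — and split by a
  Poisson pen-lift process that skips a short stretch of path, creating
  real spatial gaps. Tracing is anchored to the visible reference (scale
  and placement effects damped to 15%), with the ability signal moved into
  tremor amplitude; in-trace flags derive from distance to the reference
  with tolerance 0.025.
* **Null calibration.** `CohortSpec.null()` sets every effect to zero and
  chooses the BVSCO noise SD analytically so the labeling rule flags each
  exercise with probability `1 − 0.5^(1/3)`, making the at-risk label an
  ability-independent coin flip with P ≈ 0.5 — the condition under which
  "classifiers perform at chance" is measurable as accuracy ≈ 0.5.
* SUS responses are constructed so the transformed score lands near
  89.4 ± 9.6 (an "excellent" usability regime); a small sex effect
  (±2.5 graphemes/min) gives the exploratory sex t-tests realistic signal.

**What the generator does not emulate:** head movement and
tracker-to-screen calibration drift, pupillometry, blinks and saccade
kinematics, pen pressure/tilt/velocity, real normative tables, age effects
beyond grade, heavy-tailed completion-time outliers, and any
non-monotone ability–feature relationships. Passing tests therefore show
that the *pipeline* is correct and well calibrated under the assumed
generative structure — not that the classifier accuracies transfer to real
cohorts.

## 6. Numerical conventions and degenerate inputs

* All randomness flows from explicit integer seeds; per-subject and
  per-stream generators are derived via hashed seed sequences, so cohorts,
  subjects and single streams are independently reproducible, and the full
  pipeline reproduces its report files byte for byte.
* K-means grid ties and ranking ties break deterministically (first in
  input order); grid search ties keep the first combination in sorted-key
  order.
* Degenerate inputs: identical points make the partition fail loudly;
  empty cleaned streams mark the level missing; single-point drawings have
  zero lengths and dispersions; singleton grade groups scale to zero;
  constant features get zero Shapley attribution and are never selected;
  constant columns are flagged in correlation summaries.
* Problem sizes used by the test-suite calibration checks: cohorts of 53
  (study scale) and 200 (calibration scale), 1000-instance oracle sweeps,
  50-replicate Shapley recovery.

## 7. Known limitations

* The Pupil-style export dialect covers the common column namings; exotic
  tracker exports need a custom `GazeExportDialect`.
* The two-stage K-means partition assumes the four-panel screen geometry;
  other layouts need their own `LevelLayout`.
* `tract_discont_perc` and the dispersion conventions are package
  definitions (documented above), not standardized descriptors; compare
  across studies with care.
* With very small cohorts (< ~25 per class structure) the nested CV's
  inner folds become tiny and hyperparameter selection is noisy; the
  repeated-split baselines are reported for context, not inference.
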