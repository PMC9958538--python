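# scrivo

Screening analytics for **dysgraphia risk** in primary-school children from
serious-game sessions. Dysgraphia — handwriting production below age and
schooling expectations — is usually diagnosed only after handwriting has
fully developed, two school years too late for preventive training. Visual
perception is one of the upstream abilities implicated in handwriting, and
it can be probed *before* writing consolidates: children play gamified
visual-perception exercises (form constancy, masked form constancy, visual
closure, figure-ground search, copying, tracing) on a tablet while wearing
a head-mounted eye tracker.

`scrivo` implements the complete analysis for such sessions, for
researchers and screening-tool developers:

* **Gaze pipeline** — confidence cleaning (samples with confidence < 70%
  are discarded), two-stage K-means partitioning of the screen into task
  panels (one horizontal split on x, then vertical thirds of the right
  half on y), and seven eye-tracking metrics per level: counts of gaze
  positions and fixations, mean fixation duration, per-panel gaze
  fractions, gaze- and fixation-based *indecision* (the number of bounces
  between the target panel and the answer options), and the Standard
  Distance dispersion
  `SD = sqrt( (1/n) Σ_i [(x_i − x̄)² + (y_i − ȳ)²] )`, with per-grade
  z-scaling.
* **Drawing pipeline** — pen-stroke (tract) segmentation and the drawing
  descriptors: tract discontinuity length, fraction of discontinuous tract
  onsets, inked length, centroid, distance from the cohort center,
  dispersions from centroid and start, copying time, and out-of-trace
  length/fraction for tracing levels.
* **Normative risk labeling** — BVSCO-2 handwriting-speed scoring
  (graphemes per minute over three one-minute exercises, including the
  greedy "le"-sequence grapheme counter); a child is *at risk* when at
  least one exercise falls below the grade's normative mean minus two
  standard deviations. The System Usability Scale transform is included.
* **Risk models** — five predictor sets (game / eye / drawing /
  game+drawing / all), baseline classifiers over six repeated stratified
  80/20 splits, and the main model: a gradient-boosted tree classifier
  (LightGBM) inside stratified 5-fold nested cross-validation with an
  inner 3-fold hyperparameter grid, reported as mean ± SD of accuracy,
  precision, recall and F1 per fold. Exact tree-path-dependent Shapley
  values rank and select features.
* **Synthetic cohort generator** — the study data such analyses run on are
  typically private, so the package ships a generator in which a single
  latent handwriting-ability factor drives game times/errors, gaze
  behavior, drawing morphology *and* the BVSCO-2 counts; the risk label is
  always derived from the generated counts by the normative rule, never
  assigned. Every downstream stage is testable end to end, including null
  calibration (zero effects ⇒ chance-level classifiers).

## Worked example

```python
from scrivo import CohortSpec, PipelineConfig, gen_cohort
from scrivo.pipeline import extract_feature_table
from scrivo.model import assemble_features, nested_cv_eval

spec = CohortSpec.default(n_subjects=53, seed=1)     # study-scale cohort
records = gen_cohort(spec)
config = PipelineConfig(seed=1)
features, labels, challenging, meta = extract_feature_table(records, spec.norms, config)
print("challenging levels:", challenging)
print("at risk:", int(labels.at_risk.sum()), "of", len(labels))

matrix = assemble_features(features, labels["at_risk"], "game", challenging)
report = nested_cv_eval(matrix, seed=1)
t = report.aggregate["test"]
print("game set, nested-CV test: "
      f"accuracy={t['accuracy']['mean']:.2f}  f1={t['f1']['mean']:.2f}  recall={t['recall']['mean']:.2f}")
```

prints

```
challenging levels: ['visual_closure_hard', 'masked_form_constancy_hard']
at risk: 19 of 53
game set, nested-CV test: accuracy=0.68  f1=0.54  recall=0.55
```

The two *challenging* levels are picked by across-subject variance of
completion time and carry the eye-tracking predictors; 19 of 53 synthetic
children fall under the normative threshold in at least one handwriting
exercise; the nested-CV row is the Table-style summary for the
game-performance predictor set (train and test metrics stay close because
hyperparameters are chosen on inner folds only).

The same run from the shell:

```bash
scrivo run-all --n-subjects 53 --seed 1 --out reports
scrivo report --out reports
```

writes `features.csv`, `labels.csv`, the baselines table (repeated-split
accuracies per algorithm), the nested-CV table, per-set Shapley summaries,
an exploratory summary (correlations, sex t-tests on BVSCO scores, SUS
statistics) and a manifest; re-running with the same config reproduces all
files byte for byte. `scrivo simulate/extract/label/train/explain` expose
the individual stages, and a YAML config (`--config`) surfaces every knob
(confidence threshold, tract-gap threshold, scaling scope, cohort-center
mode, CV settings, seeds).

## Layout

```
src/scrivo/
  levels.py     level catalog, panel layouts, drawing templates
  synthetic.py  latent-ability cohort generator
  gaze.py       cleaning, K-means panels, eye-tracking metrics
  drawing.py    tract segmentation and drawing descriptors
  scoring.py    BVSCO-2 scoring, normative labels, SUS
  model.py      feature sets, baselines, nested CV, Shapley values
  io.py         eye-tracker export dialect, cohort directories
  report.py     exploratory statistics, scanpath/beeswarm plots
  pipeline.py   end-to-end orchestration
  cli.py        `scrivo` command-line interface
```

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
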