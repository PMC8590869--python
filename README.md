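# hsi — Hemodynamic Stability Index

An interpretable early-warning toolchain for hemodynamic interventions in
the ICU, exercised end-to-end on a bundled synthetic cohort generator:

* **Intervention labeling** — trailing-window trigger criteria over
  treatment records (pressor/inotrope doses, fluid boluses, PRBC
  transfusions: 700 cc/1 h, 1500 cc/4 h, 2400 cc/8 h, 3000 cc/12 h, two
  500 cc boluses in 4 h, 800 cc PRBC/24 h, conditional 500 cc PRBC rules)
  and segment construction with a >12 h gap rule.
* **Feature snapshots** — 33 physiological variables at arbitrary query
  times with forward-fill staleness limits (2 h vitals / 26 h labs and
  ventilator settings), invasive/noninvasive blood-pressure merging,
  shock-index derivation, population-mean imputation (FiO2 → 0.21,
  MAWP/PIP left missing), and operating-mode masking
  (basic / basic+labs / basic+ventilation / all).
* **Sampling** — one positive per unstable stay at a configurable lead
  time before its first segment, one random negative per stable stay,
  first-6-h exclusion, DNR/minor exclusion, and a patient-disjoint
  stratified 80/20 split.
* **Model** — gradient-boosted depth-1 stumps (200 rounds, learning rate
  0.1) whose per-variable contributions sum exactly to the raw score;
  Platt calibration; HSI = 100 × (1 − p); per-feature risk curves.
* **Uncertainty & abstention** — bootstrap model uncertainty plus
  empirical-marginal redraw of imputed/missing features; abstain when the
  confidence interval overlaps the decision threshold.
* **Evaluation** — AUC/AUPRC (own implementations, cross-checked against
  scikit-learn in tests), breakeven and fixed-specificity operating
  points, single-parameter baselines, operating-mode / lead-time /
  subgroup sweeps.
* **Synthetic cohort** — seeded generator planting stable vs.
  deteriorating trajectories whose treatments unambiguously satisfy (or
  avoid) every trigger criterion.

## CLI

```bash
hsi simulate --n-stays 1000 --unstable-fraction 0.18 --seed 7 --out cohort/
hsi label    --treatments cohort/treatments.csv --out segments.csv
hsi run      --seed 7 --out run/ --n-stays 1000      # full pipeline
```

`hsi run` executes simulate → label → sample → stats → featurize → train
→ predict → evaluate, writing plain CSV/JSON artifacts plus a manifest
into the run directory; re-running with the same config skips completed
stages, and identical configs reproduce byte-identical artifacts. See
`hsi --help` for the remaining stage-level subcommands (featurize,
sample, train, predict, evaluate) and `hsi run --config config.yaml` for
YAML-driven configuration.

## Layout

```
src/hsi/
  registry.py     variable registry, fill limits, imputation, modes
  synthetic.py    seeded cohort generator (stays/observations/treatments)
  labeler.py      trigger criteria + intervention segments
  features.py     snapshots, population stats, BP merging
  sampler.py      sample draws, exclusions, stratified split
  model.py        boosted stumps, Platt scaling, risk curves, persistence
  uncertainty.py  bootstrap + feature-redraw CIs, abstention
  evaluation.py   AUC/AUPRC, operating points, protocol sweeps
  pipeline.py     staged end-to-end runner with manifest
  diagnostics.py  behavioral constant-recovery probes
  cli.py          click entry point
```
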