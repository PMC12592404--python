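# magest

Analysis pipeline for auditory/visual magnitude-reproduction experiments:
central-tendency psychometrics, truncated-normal observer priors, Bayesian
ideal-observer response models, and mixed-model comparison — plus a synthetic
observer cohort generator that emulates the experimental design end to end.

## What it does

The pipeline analyzes long-format trial tables from duration (temporal) and
length (spatial) reproduction tasks, where each task is run in an
auditory-only baseline, a visual-only baseline, and an interleaved
audio-visual session:

1. **Preprocessing** (`magest.preprocess`) — per-cell response normalization,
   perceived-vs-real OLS fits (dof-adjusted RMSE), and participant outlier
   screening (|RMSE − group median| > 3 group SD in any session excludes the
   participant from that task).
2. **Psychometrics** (`magest.psychometrics`) — Regression Index
   (RI = 1 − slope; 0 veridical, 1 complete regression to the mean),
   intercept bias, per-stimulus sensory precision net of central tendency
   (residual variance / slope²), and modality reliability weights
   ω_A = σ_V² / (σ_A² + σ_V²).
3. **Priors** (`magest.priors`) — truncated-normal machinery: closed-form
   forward moments and inverse moment-matching by bounded least squares.
   Note: a truncated normal's variance on [a, b] cannot exceed the uniform
   variance (b − a)²/12, so the moments of a discrete equally spaced set are
   not always attainable on its own bounds; `solve_prior` surfaces this as an
   explicit infeasibility error, with a flagged `best_fit` fallback (a
   near-uniform prior) used by the model-construction path.
4. **Observer models** (`magest.models`) — four ideal observers sharing a
   Gaussian likelihood (per-participant, per-stimulus baseline precision)
   and differing in the prior: SegAudio (auditory set), SegVision (visual
   set), CTE (pooled supra-modal set), WCTE (reliability-weighted mix of the
   two segregation priors).
5. **Model comparison** (`magest.comparison`) — each model's predictions are
   scored with a linear mixed model `observed ~ stimulus + prediction +
   (1 | participant)` fitted by maximum likelihood; AIC/BIC/logLik/deviance,
   Pearson R², and participant-grouped cross-validated predicted R² are
   reported, with ΔAIC < 2 flagged as comparable support.
6. **Synthetic observers** (`magest.simulate`) — cohorts of Bayesian
   observers with affine sensory noise (floor + coef × stimulus), a
   configurable generative prior regime (`veridical`, `seg_audio`,
   `seg_vision`, `cte`, `wcte`), motor noise and bias; used for parameter and
   model recovery, standing in for the study's participant data.

Default design constants: temporal sets are nine equally spaced durations
(auditory 490–850 ms, mean 670; visual 760–1120 ms, mean 940; pooled mean
805), baseline sessions 180 trials, interleaved 360; spatial sets are six
equally spaced lengths (auditory 22–50°, mean 36; visual 5.5–33°), baseline
120, interleaved 240. Everything is overridable via a YAML/JSON config.

## CLI

```sh
# simulate a 19-participant temporal cohort under the seg_audio regime
magest simulate --task temporal --regime seg_audio --n 19 --seed 1 \
    --out trials.csv

# stage by stage
magest analyze preprocess --in trials.csv --out normalized.csv --report outliers.json
magest analyze psychometrics --in normalized.csv --out metrics.csv --precision-out precision.csv
magest analyze predict --in normalized.csv --models SegAudio,SegVision,CTE,WCTE --out predictions.csv
magest compare --observed normalized.csv --predictions predictions.csv --out table1.csv

# or everything at once (writes trials, metrics, predictions, comparison
# table, and a manifest with file digests into out/)
magest run-full --task temporal --regime seg_audio --n 19 --seed 1 --out out/

magest validate-config config.yaml
```

`run-full` is deterministic given the seed: re-running with the same config
and seed reproduces byte-identical artifacts (digests are recorded in
`manifest.json`).

## Layout

```
src/magest/
  datamodel.py      canonical trial schema, stimulus sets, config I/O
  simulate.py       synthetic Bayesian-observer cohorts
  preprocess.py     normalization, linear fits, outlier screening
  psychometrics.py  RI, sensory precision, modality weights
  priors.py         truncated-normal moments and moment-matching
  models.py         the four ideal-observer models
  comparison.py     mixed-model scoring, AIC/BIC ranking, predicted R²
  pipeline.py       stage orchestration, manifest, config validation
  cli.py            command-line interface
tests/              pytest suite; tests/test_acceptance.py holds the
                    acceptance criteria (design constants, quadrature and
                    round-trip oracles, closed-form slope, precision
                    recovery, model recovery, degeneracy, directional checks)
scripts/acceptance.py  acceptance-target report
```
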