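# cfrl

Simulation, model fitting and group-level model selection for
valence/type-asymmetric Q-learning on probabilistic two-armed bandit tasks
with factual and counterfactual feedback.

The package covers a complete analysis pipeline:

- **`cfrl.task`** — task schedules (default: 2 sessions × 4 interleaved
  contexts × 24 trials = 192 trials; Symmetric .50/.50, two Asymmetric
  .75/.25, Reversal .83/.17 with a contingency swap after 12 context-trials),
  independent ±1 outcome draws per option, agent simulation and virtual
  cohorts.
- **`cfrl.models`** — the model space (Full, Information, Valence,
  Confirmation, Perseveration, One): delta-rule updates with separate
  learning rates for positive/negative prediction errors of the
  chosen/unchosen option, softmax choice, and the learning-rate tying maps.
- **`cfrl.fitting`** — likelihood replay, bounded multi-restart MLE (for
  BIC) and MAP with gamma(1.2, scale 5) / beta(1.1, 1.1) priors (for
  learning-rate analyses), per-condition fits.
- **`cfrl.selection`** — random-effects Bayesian model selection from
  per-subject BIC-based evidences: posterior model attributions, population
  model frequencies, Monte-Carlo exceedance probabilities.
- **`cfrl.validation`** — parameter-correlation matrices, continuous
  (prior-drawn) and discrete-profile parameter-recovery experiments.
- **`cfrl.behaviour`** — preferred/correct choice rates, normalised
  learning-rate bias indices, median splits, trial-by-trial model-estimate
  curves and squared-distance model/data comparison.

## CLI

```sh
# simulate a 20-subject cohort from the Confirmation model
cfrl simulate --model Confirmation --params params.yaml --n 20 --seed 1 --out cohort.csv

# fit candidate models per subject by MLE
cfrl fit --data cohort.csv --models Full,Information,Valence,Confirmation,Perseveration,One \
         --objective mle --seed 7 --out fits.csv

# group-level Bayesian model selection from the fits
cfrl compare --fits fits.csv --models Full,Information,Valence,Confirmation --seed 7

# parameter recovery (100 prior-drawn virtual subjects)
cfrl recover --model Confirmation --n 100 --profile empirical-like --seed 7

# behavioural summary with bias indices and median split
cfrl analyse --data cohort.csv --fits map_fits.csv --experiment 2 --out summary.csv
```

`params.yaml` maps a model's free parameters to values, e.g. for the
Confirmation model:

```yaml
beta: 5.0
alpha_con: 0.4
alpha_dis: 0.1
```

Datasets are flat CSVs with columns `subject, session, context_label,
context_instance, context_trial, choice, outcome_chosen, outcome_unchosen`
(the last is empty under partial feedback). Task designs serialise to
YAML/JSON via `cfrl.io`.

## Notes

- Values are initialised to 0 per context instance (a fresh stimulus set
  per session) and stay in [−1, 1]; outcomes are coded +1/−1.
- `beta` is a scaling factor: larger values give more deterministic choice.
  It is capped at 100 during optimisation.
- One known-red test, `test_bms_brute_force_agreement_generic_2dp`,
  documents that the mean-field variational model-selection scheme deviates
  from the exact Dirichlet-multinomial posterior by up to ~0.1 on
  weak-evidence problems with very few subjects; the dominance and symmetry
  regimes agree with brute force to well under 0.005.
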