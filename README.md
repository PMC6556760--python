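# platsim

A scriptable simulator for planning platform-adaptive clinical trials.
It simulates single Bayesian adaptive/platform trials under user-specified
truth scenarios, estimates design operating characteristics (type I error,
power, expected sample size / cost / duration) over many replicates against
a conventional fixed-sample comparator, and includes a conventional
sample-size calculator for sizing that comparator.

## What it models

- **Outcomes**: binary (beta-binomial model) or continuous (conjugate
  Gaussian model for the arm mean with a plug-in pooled outcome SD), with a
  configurable benefit direction and an optional monitored-only secondary
  outcome.
- **Adaptation rules**, all driven by Bayesian posterior probabilities
  evaluated at equally spaced interim looks:
  - early stopping when any arm's probability of being best exceeds a
    superiority threshold (e.g. 99%);
  - dropping a treatment arm whose probability of being best falls below a
    futility threshold (e.g. 1%);
  - dropping a treatment arm once there is high certainty (e.g. 95%) that
    its effect vs control is smaller than a minimally important margin
    (e.g. a 20% relative risk reduction);
  - platform behavior: a queued arm replaces a dropped one, and an optional
    perpetual mode continues the trial as a new two-arm comparison against
    the previous stage's winner (up to a hard cap).
- **Allocation**: equal randomization, or response-adaptive randomization
  using the ratio of square roots of the per-arm superiority probabilities,
  with equal allocation during a burn-in phase and per-patient reweighting
  afterwards.
- **Adherence**: each treatment-arm patient responds from their own arm's
  distribution with probability `adherence`, otherwise from the control's
  (intent-to-treat dilution).
- **Accounting**: linear cost per enrolled patient; duration equals total
  enrollment divided by a constant accrual rate.

Every source of randomness flows from a single master seed; replicate `i`
uses `SeedSequence(seed, spawn_key=(stream, i))`, so results are exactly
reproducible and increasing the replicate count never reshuffles earlier
replicates.

## CLI

```sh
# emit a canonical example scenario
platsim fixture alt-2arm --out scenario.yaml

# simulate one trial: decision log, superiority-by-look table, JSON dump
platsim simulate --config scenario.yaml --seed 7 --out-dir out/

# operating characteristics over many replicates (vs the conventional design)
platsim evaluate --config scenario.yaml --n-sims 200 --out-dir out/ [--plot]

# conventional sample-size calculator
platsim samplesize --outcome binary --p1 0.4 --p2 0.3 --alpha 0.05 --power 0.8
platsim samplesize --outcome binary --effects 0.3,0.4,0.55 --multiplicity bonferroni
```

Scenario files are YAML (JSON also loads); unknown keys and out-of-range
values are rejected with messages naming the field. See
`platsim fixture null-2arm` for a complete annotated-by-example schema:
top-level keys `schema_version`, `outcome`, `arms`, `rules`, `simulation`.

## Library

```python
import numpy as np
from platsim import make_fixture, simulate_trial, evaluate_design

cfg = make_fixture("platform-3arm")
result = simulate_trial(cfg.to_arm_specs(), cfg.to_design_rules(),
                        np.random.default_rng(7))
summary = evaluate_design(cfg.to_arm_specs(), cfg.to_design_rules(),
                          n_sims=200, seed=7)
```

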