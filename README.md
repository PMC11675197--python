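# oua — Ornstein–Uhlenbeck adaptation

Gradient-free, continuous-time learning. Each model parameter follows a
mean-reverting Ornstein–Uhlenbeck (OU) process

```
dθ = λ (μ − θ) dt + Σ dW
```

whose mean μ is nudged by a global reward-prediction-error (RPE) signal

```
dμ = η δr (θ − μ) dt,      δr = r − r̄,      dr̄ = ρ (r − r̄) dt.
```

Random excursions of θ that raise the reward above its running average
pull the mean toward them; below-average excursions push it away. No
gradients of the model with respect to its parameters are ever needed,
so the same rule trains static readouts, recurrent dynamics and
closed-loop controllers. The cumulative reward `G(t) = ∫ r dτ` tracks
learning progress. A meta-learning variant applies the identical OU+RPE
mechanism to the exploration magnitude σ itself, growing exploration
when the environment shifts and shrinking it when the task is stable.

## Quick start

```python
from oua import (HyperParams, IntegratorConfig, SystemModel,
                 simulate, single_param_task)

task = single_param_task(T=1000.0)           # recover θ* = 1 in y = tanh(θ x)
hp = HyperParams(lam=1.0, sigma=0.3, rho=1.0, eta=1.0)
cfg = IntegratorConfig(T=1000.0, dt=0.05, seed=1, n_trials=15)
ens = simulate(SystemModel.static_tanh(1), task, hp, cfg)
print(ens.median_mu_T())      # [1.0631...]  (ground truth 1.0)
```

The learner never sees a gradient: 15 independent trials each integrate
the coupled SDE system for 1000 time units (Δt = 0.05, Euler–Heun) and
the median terminal mean parameter lands within 7% of the ground truth.

## Experiments

Six named experiments ship with calibrated defaults:

| name               | task                                             | outcome (seed 1, 15 trials)        |
|--------------------|--------------------------------------------------|------------------------------------|
| `single_param`     | recover θ*=1 in y = tanh(θx)                     | median μ(T) = 1.063                |
| `multi_param`      | recover 6-vector θ* from multi-sine inputs       | all components within ±0.2         |
| `weather_surrogate`| 24 h-ahead regression, ZCA-whitened features     | test MSE 0.326 (SGD baseline 0.359)|
| `ctrnn`            | recover 3 CTRNN weights from input–output data   | median μ(T) = (0.33, 0.67, 0.96)   |
| `sdi`              | stabilise a stochastic double integrator         | learned gains negative, 14/15 seeds|
| `meta_volatile`    | target flips sign mid-run; σ is itself learned   | median μ(T) = −0.955 (truth −1)    |

Run them from the command line:

```bash
oua run single_param --seed 1 --out results/single
oua run sdi --out results/sdi --plot
oua sweep single_param --param sigma --grid 0.0,0.1,0.3,0.6
oua baseline sgd --synthetic
```

Each run writes tidy trajectory CSVs, a JSON summary (terminal μ,
cumulative rewards for the learning run, a matched no-learning baseline
and the frozen-parameter deployment, terminal RPE statistics) and a
config echo; `--plot` adds overview PNGs. YAML files passed via
`--config` overlay any default (schema mirrors the `config` block of a
written summary).

The weather experiment uses a bundled synthetic surrogate of an hourly
weather table (six correlated features, one dominant predictor); a CSV
with the same schema can be supplied for parity runs
(`oua baseline sgd --data file.csv`, `oua.tasks.load_weather_csv`).

## Package layout

- `oua.core` — the learning-rule primitives (reward filter, RPE, OU
  step, mean step, stationary covariance, RPE stability margin).
- `oua.models` — static tanh/linear readouts and the one-unit CTRNN.
- `oua.integrator` — Euler–Heun integration of the coupled system,
  reproducible per-trial noise streams, trajectory recording, frozen
  (θ = μ(T)) deployment.
- `oua.tasks` — the experiment environments, ZCA whitening, the
  synthetic weather surrogate.
- `oua.meta` — learnable-σ dynamics and the volatile-target experiment.
- `oua.experiments` / `oua.cli` — named experiment configs, the
  sensitivity sweep, the SGD baseline, result serialisation.

See `docs/methods.md` for the mathematical model, all default
parameters, the stability analysis behind the two deviations from the
naive rule (RPE clipping and episodic resets for the control task), and
known limitations.
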