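"""Named experiments, the hyper-parameter sensitivity sweep and the SGD baseline.

Each named experiment bundles the task, the model and the
reference hyper-parameters into an :class:`ExperimentConfig`;
:func:`run_experiment` integrates the ensemble, evaluates a no-learning
baseline and a frozen-parameter deployment on the same grid, and
optionally serialises everything (tidy trajectory CSV, JSON summary,
config echo) to an output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import HyperParams
from .integrator import (
    Ensemble,
    IntegratorConfig,
    freeze_parameters,
    frozen_rollout,
    simulate,
)
from .meta import MetaParams, run_meta_experiment
from .models import SystemModel
from .tasks import (
    WEATHER_COLUMNS,
    TaskSpec,
    ctrnn_task,
    multi_sine_task,
    sdi_task,
    single_param_task,
    synthetic_weather_generator,
    volatile_task,
    weather_task,
    zca_whiten,
)

__all__ = [
    "EXPERIMENTS",
    "ExperimentConfig",
    "default_config",
    "build_task_and_model",
    "run_experiment",
    "sensitivity_sweep",
    "SGDResult",
    "sgd_baseline",
    "weather_dataset",
]

EXPERIMENTS = (
    "single_param",
    "multi_param",
    "weather_surrogate",
    "ctrnn",
    "sdi",
    "meta_volatile",
)


@dataclass
class ExperimentConfig:
    """A fully specified, reproducible experiment run."""

    name: str
    hp: HyperParams
    integrator: IntegratorConfig
    task_kwargs: dict = field(default_factory=dict)
    meta: MetaParams | None = None
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}"
            )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "hyper_params": {
                "lam": self.hp.lam,
                "sigma": np.atleast_1d(self.hp.sigma).tolist(),
                "rho": self.hp.rho,
                "eta": self.hp.eta,
                "rpe_margin": (self.hp.rpe_margin
                               if np.isfinite(self.hp.rpe_margin) else None),
            },
            "integrator": dataclasses.asdict(self.integrator),
            "task_kwargs": dict(self.task_kwargs),
        }
        if self.meta is not None:
            d["meta"] = dataclasses.asdict(self.meta)
        return d


def default_config(name: str, seed: int = 0, n_trials: int = 15,
                   out_dir=None) -> ExperimentConfig:
    """Reference hyper-parameters and calibrated horizons per experiment.

    Horizons are package choices (chosen once so the RPE stabilises);
    the remaining values follow the reference configurations.  Two
    stability deviations for the recurrent and control experiments
    (adaptation rate eta=5 instead of 50 for the CTRNN; sigma=0.2,
    episodic resets and the RPE stability margin for the double
    integrator) are documented in docs/methods.md.
    """
    if name == "single_param":
        hp = HyperParams(lam=1.0, sigma=0.3, rho=1.0, eta=1.0)
        cfg = IntegratorConfig(T=1000.0, seed=seed, n_trials=n_trials,
                               record_stride=10)
        kwargs: dict = {}
    elif name == "multi_param":
        hp = HyperParams(lam=1.0, sigma=0.2, rho=1.0, eta=1.0)
        cfg = IntegratorConfig(T=3000.0, seed=seed, n_trials=n_trials,
                               record_stride=10)
        kwargs = {}
    elif name == "weather_surrogate":
        hp = HyperParams(lam=1.0, sigma=0.05, rho=1.0, eta=0.1)
        # T is set from the data span when the task is built
        cfg = IntegratorConfig(T=1.0, seed=seed, n_trials=n_trials,
                               record_stride=100)
        kwargs = {"data_seed": 7, "n_samples": 3000, "train_frac": 0.8,
                  "passes": 5}
    elif name == "ctrnn":
        hp = HyperParams(lam=1.0, sigma=0.2, rho=1.0, eta=5.0)
        cfg = IntegratorConfig(T=1000.0, seed=seed, n_trials=n_trials,
                               record_stride=10)
        kwargs = {}
    elif name == "sdi":
        hp = HyperParams(lam=1.0, sigma=0.2, rho=2.0, eta=50.0, rpe_margin=0.9)
        cfg = IntegratorConfig(T=2000.0, seed=seed, n_trials=n_trials,
                               record_stride=20)
        kwargs = {"reset_interval": 20.0}
    elif name == "meta_volatile":
        hp = HyperParams(lam=1.0, sigma=0.15, rho=1.0, eta=1.0)
        cfg = IntegratorConfig(T=2000.0, seed=seed, n_trials=n_trials,
                               record_stride=10)
        return ExperimentConfig(name=name, hp=hp, integrator=cfg,
                                meta=MetaParams(), out_dir=out_dir)
    else:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    return ExperimentConfig(name=name, hp=hp, integrator=cfg,
                            task_kwargs=kwargs, out_dir=out_dir)


# --------------------------------------------------------------------------
# data plumbing for the regression experiment
# --------------------------------------------------------------------------

def weather_dataset(data_seed: int = 7, n_samples: int = 3000,
                    train_frac: float = 0.8, frame: pd.DataFrame | None = None):
    """Chronological train/test split with ZCA fitted on the train segment.

    Returns ``(X_train, y_train, X_test, y_test, whitener)`` with both
    feature tables already whitened by the train-fitted transform.  A
    user-supplied ``frame`` (schema of :func:`load_weather_csv`)
    replaces the synthetic table.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if frame is None:
        frame, _ = synthetic_weather_generator(seed=data_seed,
                                               n_samples=n_samples)
    X = frame[WEATHER_COLUMNS].to_numpy(dtype=float)
    y = frame["target"].to_numpy(dtype=float)
    n_train = int(train_frac * len(y))
    if n_train < 2 or len(y) - n_train < 2:
        raise ValueError("split leaves too few samples on one side")
    X_train, whitener = zca_whiten(X[:n_train])
    X_test = whitener(X[n_train:])
    return X_train, y[:n_train], X_test, y[n_train:], whitener


def build_task_and_model(config: ExperimentConfig):
    """Instantiate the TaskSpec and SystemModel for a named experiment.

    For the weather experiment this also returns the held-out data as
    ``extras`` (empty dict otherwise), and the config's horizon is
    overridden by the data span.
    """
    kw = dict(config.task_kwargs)
    extras: dict = {}
    name = config.name
    if name == "single_param":
        task = single_param_task(T=config.integrator.T, **kw)
        model = SystemModel.static_tanh(1)
    elif name == "multi_param":
        task = multi_sine_task(T=config.integrator.T, **kw)
        model = SystemModel.static_tanh(task.n_inputs)
    elif name == "weather_surrogate":
        passes = kw.pop("passes", 5)
        frame = kw.pop("frame", None)
        Xtr, ytr, Xte, yte, whitener = weather_dataset(
            data_seed=kw.pop("data_seed", 7),
            n_samples=kw.pop("n_samples", 3000),
            train_frac=kw.pop("train_frac", 0.8),
            frame=frame,
        )
        task = weather_task(Xtr, ytr, theta0=np.zeros(Xtr.shape[1]),
                            passes=passes, **kw)
        model = SystemModel.static_linear(task.n_inputs)
        extras = {"X_train": Xtr, "y_train": ytr, "X_test": Xte,
                  "y_test": yte, "whitener": whitener}
    elif name == "ctrnn":
        task = ctrnn_task(T=config.integrator.T, **kw)
        model = SystemModel.ctrnn()
    elif name == "sdi":
        task = sdi_task(T=config.integrator.T, **kw)
        model = SystemModel.static_linear(2)
    elif name == "meta_volatile":
        task = volatile_task(T=config.integrator.T, **kw)
        model = SystemModel.static_tanh(1)
    else:
        raise ValueError(f"unknown experiment {name!r}")
    return task, model, extras


# --------------------------------------------------------------------------
# SGD baseline
# --------------------------------------------------------------------------

@dataclass
class SGDResult:
    """Fitted linear baseline and its held-out metrics."""

    coef: np.ndarray
    mse: float
    pearson: float


def _regression_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    mse = float(np.mean((pred - truth) ** 2))
    sp = pred.std()
    st = truth.std()
    pearson = (float(np.corrcoef(pred, truth)[0, 1])
               if sp > 0 and st > 0 else 0.0)
    return mse, pearson


def sgd_baseline(dataset, learning_rate: float = 0.01, epochs: int = 10,
                 seed: int = 0) -> SGDResult:
    """Online SGD on squared loss for the linear readout.

    ``dataset`` is ``(X_train, y_train, X_test, y_test)``; metrics are
    computed exactly as for the frozen OUA model (same split, same
    whitening already applied to the tables).  Divergence is reported
    with the offending learning rate.
    """
    X_train, y_train, X_test, y_test = dataset
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    if epochs < 0:
        raise ValueError("epochs must be non-negative")
    rng = np.random.default_rng(seed)
    coef = rng.normal(0.0, 1e-3, size=X_train.shape[1])
    for _ in range(epochs):
        for x, t in zip(X_train, y_train):
            coef = coef - learning_rate * (coef @ x - t) * x
        if not np.all(np.isfinite(coef)):
            raise FloatingPointError(
                f"SGD diverged at learning_rate={learning_rate}"
            )
    mse, pearson = _regression_metrics(np.asarray(X_test) @ coef,
                                       np.asarray(y_test))
    return SGDResult(coef=coef, mse=mse, pearson=pearson)


# --------------------------------------------------------------------------
# experiment runner
# --------------------------------------------------------------------------

def _baseline_run(model, task: TaskSpec, hp: HyperParams,
                  cfg: IntegratorConfig) -> Ensemble:
    """The dashed-line reference: identical grid and seeds, no learning."""
    quiet = HyperParams(lam=hp.lam, sigma=0.0, rho=hp.rho, eta=0.0,
                        rpe_margin=hp.rpe_margin)
    return simulate(model, task, quiet, cfg)


def run_experiment(config: ExperimentConfig, log_every: int = 0) -> dict:
    """Run one named experiment end to end and return the JSON-able summary.

    The summary holds the terminal mean parameters, cumulative rewards
    for the learning run, the matched no-learning baseline and the
    frozen-parameter deployment, and terminal RPE statistics.  With
    ``config.out_dir`` set, trajectories (tidy CSV), the summary and a
    config echo are written there.  ``log_every`` > 0 prints one
    structured progress line per that many recorded steps.
    """
    task, model, extras = build_task_and_model(config)
    cfg = config.integrator
    if config.name == "weather_surrogate":
        cfg = dataclasses.replace(cfg, T=task.T)

    if config.name == "meta_volatile":
        res = run_meta_experiment(cfg, hp=config.hp, meta=config.meta,
                                  t_switch=task.t_switch, rbar0=task.rbar0)
        ens = res.learnable
        summary = {"experiment": config.name, "config": config.to_dict(),
                   "meta": res.summary}
    else:
        ens = simulate(model, task, config.hp, cfg, meta=config.meta)
        summary = {"experiment": config.name, "config": config.to_dict()}
        res = None

    if log_every > 0:
        tr = ens[0]
        for j in range(0, tr.times.size, log_every):
            gap = float(np.linalg.norm(tr.theta_path[j] - tr.mu_path[j]))
            print(f"t={tr.times[j]:.1f} r={tr.r_path[j]:.4f} "
                  f"delta_r={tr.delta_r_path[j]:.4f} |theta-mu|={gap:.4f}")

    baseline = _baseline_run(model, task, config.hp, cfg)
    frozen = freeze_parameters(ens, model)

    summary.update({
        "median_mu_T": ens.median_mu_T().tolist(),
        "mu_T": ens.mu_T().tolist(),
        "G_T_learning": ens.G_T().tolist(),
        "G_T_baseline": baseline.G_T().tolist(),
        "final_delta_r_mean": ens.final_delta_r_mean().tolist(),
        "frozen_theta": frozen.theta.tolist(),
    })
    if task.theta_star is not None:
        summary["theta_star"] = task.theta_star.tolist()

    if config.name == "weather_surrogate":
        X_test, y_test = extras["X_test"], extras["y_test"]
        mse, pearson = _regression_metrics(frozen.predict(X_test), y_test)
        sgd = sgd_baseline((extras["X_train"], extras["y_train"],
                            X_test, y_test), seed=cfg.seed)
        summary["test"] = {
            "oua_mse": mse, "oua_pearson": pearson,
            "sgd_mse": sgd.mse, "sgd_pearson": sgd.pearson,
            "sgd_coef": sgd.coef.tolist(),
        }
    else:
        roll_task = task
        if config.name == "sdi":
            # evaluate the frozen controller on an uninterrupted episode
            roll_cfg = dataclasses.replace(cfg, T=400.0,
                                           seed=cfg.seed + cfg.n_trials)
        else:
            roll_cfg = cfg
        roll = frozen_rollout(frozen, roll_task, roll_cfg)
        summary["G_T_frozen"] = roll.G_T().tolist()
        if config.name == "sdi":
            k = int(0.8 * roll.times.size)
            mean_pos = [float(tr.z_path[k:, 0].mean()) for tr in roll]
            null = frozen_rollout(
                dataclasses.replace(frozen, theta=np.zeros_like(frozen.theta)),
                roll_task, roll_cfg)
            null_pos = [float(tr.z_path[k:, 0].mean()) for tr in null]
            summary["frozen_mean_position"] = mean_pos
            summary["baseline_mean_position"] = null_pos

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ens.write_csv(out / "trajectories.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2))
        if res is not None:
            res.fixed.write_csv(out / "trajectories_fixed_sigma.csv")
    return summary


# --------------------------------------------------------------------------
# sensitivity sweep (final G(T) vs. hyper-parameter value)
# --------------------------------------------------------------------------

SWEEPABLE = ("lam", "sigma", "rho", "eta")


def sensitivity_sweep(config: ExperimentConfig, param_name: str,
                      grid) -> pd.DataFrame:
    """Mean and dispersion of G(T) per hyper-parameter value, plus reference.

    The no-learning reference (sigma = 0, eta = 0) is computed once on
    the same seeds and repeated on every row of the returned table.
    """
    if param_name not in SWEEPABLE:
        raise ValueError(f"param_name must be one of {SWEEPABLE}")
    grid = [float(g) for g in grid]
    if not grid or not np.all(np.isfinite(grid)):
        raise ValueError("grid must be non-empty and finite")
    task, model, _ = build_task_and_model(config)
    cfg = config.integrator
    if config.name == "weather_surrogate":
        cfg = dataclasses.replace(cfg, T=task.T)
    reference = _baseline_run(model, task, config.hp, cfg).G_T()
    rows = []
    for value in grid:
        hp = dataclasses.replace(config.hp, **{param_name: value})
        G = simulate(model, task, hp, cfg, meta=config.meta).G_T()
        rows.append({
            "param": param_name,
            "value": value,
            "G_mean": float(G.mean()),
            "G_std": float(G.std(ddof=1)) if G.size > 1 else 0.0,
            "G_median": float(np.median(G)),
            "G_reference_mean": float(reference.mean()),
        })
    return pd.DataFrame(rows)
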