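"""Fixed-step stochastic integration of the coupled inference-learning system.

The learner variables (theta, mu, rbar, G), the model's latent state
and — when meta-learning is enabled — the diffusion coefficient sigma
and its mean are integrated jointly as one system with an Euler-Heun
scheme: a Heun (two-stage, trapezoidal) correction is applied to every
drift term and the diffusion increments are added once per step.  All
noise in the system is additive, for which this scheme has strong order
1.0 and coincides with the Stratonovich Euler-Heun; with zero diffusion
it reduces exactly to Heun's ODE method (deterministic order 2).

Both Heun stages evaluate the full coupled drift from a single state
snapshot, so no variable sees another's mid-step update and results do
not depend on an arbitrary update ordering.

Ensembles of independent trials integrate vectorised over a trial axis.
Each trial owns one random generator seeded ``seed + trial_index``,
whose stream is partitioned deterministically: parameter Wiener
increments first, then (if enabled) the sigma-process increments, then
environment process noise, then observation noise.  Recording therefore
never changes the draws, and disabling any optional block leaves the
remaining streams untouched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from .core import HyperParams, clipped_rpe
from .models import CTRNN, STATIC_LINEAR, STATIC_TANH, SystemModel
from .tasks import TaskSpec, quadratic_reward

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "Ensemble",
    "wiener_increments",
    "euler_heun_step",
    "simulate",
    "freeze_parameters",
    "frozen_rollout",
    "FrozenModel",
    "CubicHermiteBackward",
    "interpolate_inputs",
]


@dataclass
class IntegratorConfig:
    """Grid, seeding and recording options for one ensemble run."""

    T: float
    dt: float = 0.05
    t0: float = 0.0
    seed: int = 0
    n_trials: int = 15
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T <= self.t0:
            raise ValueError("horizon must exceed the start time")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round((self.T - self.t0) / self.dt))

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)


def wiener_increments(seed: int, n_steps: int, n_dims: int, dt: float) -> np.ndarray:
    """I.i.d. Gaussian increments, mean 0 and variance ``dt`` per entry.

    Deterministic in the seed: the same seed reproduces the array
    bitwise.
    """
    if n_steps < 1 or n_dims < 1:
        raise ValueError("n_steps and n_dims must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(dt), size=(n_steps, n_dims))


def euler_heun_step(
    drift: Callable[[float, np.ndarray], np.ndarray],
    state: np.ndarray,
    t: float,
    dt: float,
    noise: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One Euler-Heun step of ``dX = f(t, X) dt + (noise per step)``.

    ``noise`` is the full diffusion increment for the step (e.g.
    ``sigma * dW``); it is added once, in both the predictor and the
    final update.  With ``noise = 0`` this is exactly Heun's method.
    """
    f1 = drift(t, state)
    predictor = state + f1 * dt + noise
    f2 = drift(t + dt, predictor)
    return state + 0.5 * (f1 + f2) * dt + noise


# --------------------------------------------------------------------------
# input interpolation
# --------------------------------------------------------------------------

class CubicHermiteBackward:
    """Cubic Hermite interpolant with backward-difference slopes.

    Exact at the knots and reproduces linear data exactly.  Queries
    outside the sample range raise rather than extrapolate.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("need at least two time-ordered samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        slopes = np.empty_like(values)
        slopes[1:] = np.diff(values, axis=0) / np.diff(times)
        slopes[0] = slopes[1]
        self._spline = CubicHermiteSpline(times, values, slopes, extrapolate=False)
        self.t_min = float(times[0])
        self.t_max = float(times[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_min) or np.any(t > self.t_max):
            raise ValueError(
                f"query outside the sample range [{self.t_min}, {self.t_max}]"
            )
        return self._spline(t)


def interpolate_inputs(sample_times: np.ndarray, samples: np.ndarray, t):
    """Evaluate the backward-difference cubic Hermite interpolant at ``t``."""
    return CubicHermiteBackward(sample_times, samples)(t)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed record of one trial's state variables and rewards."""

    times: np.ndarray
    theta_path: np.ndarray
    mu_path: np.ndarray
    rbar_path: np.ndarray
    r_path: np.ndarray
    delta_r_path: np.ndarray
    G_path: np.ndarray
    y_path: np.ndarray
    z_path: np.ndarray | None = None
    sigma_path: np.ndarray | None = None
    mu_sigma_path: np.ndarray | None = None
    seed: int = 0

    @property
    def mu_T(self) -> np.ndarray:
        return self.mu_path[-1]

    @property
    def theta_T(self) -> np.ndarray:
        return self.theta_path[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-time table of the recorded variables."""
        data = {
            "time": self.times,
            "r": self.r_path,
            "delta_r": self.delta_r_path,
            "rbar": self.rbar_path,
            "G": self.G_path,
            "y": self.y_path,
        }
        for j in range(self.theta_path.shape[1]):
            data[f"theta_{j}"] = self.theta_path[:, j]
            data[f"mu_{j}"] = self.mu_path[:, j]
        if self.z_path is not None:
            for j in range(self.z_path.shape[1]):
                data[f"z_{j}"] = self.z_path[:, j]
        if self.sigma_path is not None:
            data["sigma"] = self.sigma_path
            data["mu_sigma"] = self.mu_sigma_path
        frame = pd.DataFrame(data)
        frame.insert(0, "seed", self.seed)
        return frame


class Ensemble:
    """A set of independent trials integrated on a shared grid."""

    def __init__(self, trajectories: list[Trajectory], config: IntegratorConfig,
                 hp: HyperParams):
        self.trajectories = trajectories
        self.config = config
        self.hp = hp

    def __len__(self) -> int:
        return len(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    def mu_T(self) -> np.ndarray:
        """Final mean parameters, one row per trial."""
        return np.stack([tr.mu_T for tr in self.trajectories])

    def median_mu_T(self) -> np.ndarray:
        return np.median(self.mu_T(), axis=0)

    def G_T(self) -> np.ndarray:
        return np.asarray([tr.G_path[-1] for tr in self.trajectories])

    def final_delta_r_mean(self, frac: float = 0.1) -> np.ndarray:
        """Per-trial time-average of the RPE over the final ``frac`` of the run."""
        k = max(1, int(round(frac * self.times.size)))
        return np.asarray([tr.delta_r_path[-k:].mean() for tr in self.trajectories])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for i, tr in enumerate(self.trajectories):
            f = tr.to_frame()
            f.insert(0, "trial", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        """JSON-serialisable run summary (config, seeds, terminal values)."""
        return {
            "config": dataclasses.asdict(self.config),
            "hyper_params": {
                "lam": self.hp.lam,
                "sigma": np.atleast_1d(self.hp.sigma).tolist(),
                "rho": self.hp.rho,
                "eta": self.hp.eta,
                "rpe_margin": (self.hp.rpe_margin
                               if np.isfinite(self.hp.rpe_margin) else None),
            },
            "seeds": [tr.seed for tr in self.trajectories],
            "mu_T": self.mu_T().tolist(),
            "G_T": self.G_T().tolist(),
            "final_delta_r_mean": self.final_delta_r_mean().tolist(),
        }

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


# --------------------------------------------------------------------------
# coupled systems (inference side, vectorised over trials)
# --------------------------------------------------------------------------

class _StaticSystem:
    """Static readout on a precomputed input/target grid."""

    aux_dim = 0
    env_noise_dim = 0
    obs_noise_dim = 0

    def __init__(self, model: SystemModel, task: TaskSpec, times: np.ndarray):
        self.bounded = model.kind == STATIC_TANH
        self.x = task.input_grid(times)  # (K, n_in)
        self.y_star = np.asarray(task.target_grid(times, self.x), dtype=float)

    def io(self, k, theta, aux, eps):
        act = theta @ self.x[k]
        y = np.tanh(act) if self.bounded else act
        r = quadratic_reward(y, self.y_star[k])
        return y, r, None


class _CTRNNSystem:
    """One-unit recurrent model tracking a teacher-generated target."""

    aux_dim = 1
    env_noise_dim = 0
    obs_noise_dim = 0

    def __init__(self, model: SystemModel, task: TaskSpec, times: np.ndarray):
        self.f = model.nonlinearity
        self.x = task.input_grid(times)[:, 0]  # scalar input
        self.y_star = np.asarray(task.target_grid(times, task.input_grid(times)),
                                 dtype=float)

    def io(self, k, theta, aux, eps):
        z = aux[:, 0]
        y = theta[:, 2] * z
        r = quadratic_reward(y, self.y_star[k])
        dz = self.f(theta[:, 0] * z + theta[:, 1] * self.x[k]) - z
        return y, r, dz[:, None]


class _SDISystem:
    """Double-integrator environment coupled to a linear feedback agent."""

    aux_dim = 2
    env_noise_dim = 1
    obs_noise_dim = 2

    def __init__(self, model: SystemModel, task: TaskSpec, times: np.ndarray):
        env = task.env
        self.alpha = env.alpha
        self.beta = env.beta
        self.gamma = env.gamma

    def io(self, k, theta, aux, eps):
        obs = aux + self.beta * eps  # (m, 2)
        y = np.sum(theta * obs, axis=-1)
        r = -0.5 * np.sum(aux * aux, axis=-1) - 0.5 * y * y
        drift = np.column_stack([aux[:, 1], -self.gamma * aux[:, 1] + y])
        return y, r, drift


def _build_system(model: SystemModel, task: TaskSpec, times: np.ndarray):
    if task.env is not None:
        return _SDISystem(model, task, times)
    if model.kind == CTRNN:
        return _CTRNNSystem(model, task, times)
    if model.kind in (STATIC_TANH, STATIC_LINEAR):
        return _StaticSystem(model, task, times)
    raise ValueError(f"no coupled system for model kind {model.kind!r}")


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _first_nonfinite(S, slices) -> str:
    for name, sl in slices.items():
        if not np.all(np.isfinite(S[:, sl])):
            return name
    return "state"


def simulate(
    model: SystemModel,
    task: TaskSpec,
    hp: HyperParams,
    cfg: IntegratorConfig,
    meta=None,
) -> Ensemble:
    """Integrate the coupled inference-learning system over [t0, T].

    Returns an :class:`Ensemble` of ``cfg.n_trials`` independent
    trajectories (trial ``i`` is seeded ``cfg.seed + i``).  When
    ``meta`` (a :class:`oua.meta.MetaParams`) is given, the diffusion
    coefficient sigma and its mean are integrated alongside with their
    own OU / RPE-modulated dynamics, and sigma multiplies the parameter
    noise instead of ``hp.sigma``.
    """
    n = model.n_params
    if task.theta0.size != n or task.mu0.size != n:
        raise ValueError(
            f"task initial conditions of length {task.theta0.size} do not match "
            f"the model's {n} parameters"
        )
    times = cfg.times()
    n_steps = cfg.n_steps
    m = cfg.n_trials
    dt = cfg.dt
    system = _build_system(model, task, times)
    d = system.aux_dim
    if d and task.aux0.size != d:
        raise ValueError("task aux0 does not match the system's latent dimension")

    # state layout: [theta | mu | rbar | G | aux | (sigma, mu_sigma)]
    i_rbar = 2 * n
    i_G = 2 * n + 1
    i_aux = slice(2 * n + 2, 2 * n + 2 + d)
    K = 2 * n + 2 + d + (2 if meta is not None else 0)
    i_sig = 2 * n + 2 + d
    i_musig = i_sig + 1
    slices = {"theta": slice(0, n), "mu": slice(n, 2 * n),
              "rbar": slice(i_rbar, i_rbar + 1), "G": slice(i_G, i_G + 1),
              "latent state": i_aux}
    if meta is not None:
        slices["sigma"] = slice(i_sig, K)

    # --- noise streams, one generator per trial, fixed partition order ---
    dW_theta = np.empty((n_steps, m, n))
    dW_sigma = np.empty((n_steps, m)) if meta is not None else None
    d_env = system.env_noise_dim
    dW_env = np.empty((n_steps, m, d_env)) if d_env else None
    o = system.obs_noise_dim
    eps_obs = np.empty((n_steps + 1, m, o)) if o else None
    root = np.sqrt(dt)
    seeds = [int(cfg.seed) + i for i in range(m)]
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        dW_theta[:, i, :] = rng.normal(0.0, root, size=(n_steps, n))
        if dW_sigma is not None:
            dW_sigma[:, i] = rng.normal(0.0, root, size=n_steps)
        if dW_env is not None:
            dW_env[:, i, :] = rng.normal(0.0, root, size=(n_steps, d_env))
        if eps_obs is not None:
            eps_obs[:, i, :] = rng.standard_normal(size=(n_steps + 1, o))

    # --- initial state ---
    S = np.empty((m, K))
    S[:, :n] = task.theta0
    S[:, n:2 * n] = task.mu0
    S[:, i_rbar] = task.rbar0
    S[:, i_G] = 0.0
    if d:
        S[:, i_aux] = task.aux0
    if meta is not None:
        S[:, i_sig] = meta.sigma0
        S[:, i_musig] = meta.mu_sigma0
    sigma_vec = hp.sigma_vector(n)

    lam, eta, rho = hp.lam, hp.eta, hp.rho
    rpe_bound = hp.rpe_bound()
    t0 = cfg.t0
    cache: list[tuple] = []

    def drift(t: float, X: np.ndarray) -> np.ndarray:
        k = int(round((t - t0) / dt))
        theta = X[:, :n]
        mu = X[:, n:2 * n]
        rbar = X[:, i_rbar]
        aux = X[:, i_aux]
        eps = eps_obs[k] if eps_obs is not None else None
        y, r, aux_drift = system.io(k, theta, aux, eps)
        delta_r = r - rbar
        delta_mu = clipped_rpe(delta_r, rpe_bound)
        dX = np.empty_like(X)
        dX[:, :n] = lam * (mu - theta)
        dX[:, n:2 * n] = eta * delta_mu[:, None] * (theta - mu)
        dX[:, i_rbar] = rho * delta_r
        dX[:, i_G] = r
        if d:
            dX[:, i_aux] = aux_drift
        if meta is not None:
            sig = X[:, i_sig]
            musig = X[:, i_musig]
            dX[:, i_sig] = meta.lam_sigma * (musig - sig)
            dX[:, i_musig] = meta.eta_sigma * delta_r * (sig - musig)
        cache.append((y, r, delta_r))
        return dX

    # --- recording buffers ---
    rec_idx = list(range(0, n_steps + 1, cfg.record_stride))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    rec_pos = {k: j for j, k in enumerate(rec_idx)}
    n_rec = len(rec_idx)
    R = {
        "theta": np.empty((n_rec, m, n)),
        "mu": np.empty((n_rec, m, n)),
        "rbar": np.empty((n_rec, m)),
        "G": np.empty((n_rec, m)),
        "r": np.empty((n_rec, m)),
        "delta_r": np.empty((n_rec, m)),
        "y": np.empty((n_rec, m)),
    }
    if d:
        R["z"] = np.empty((n_rec, m, d))
    if meta is not None:
        R["sigma"] = np.empty((n_rec, m))
        R["mu_sigma"] = np.empty((n_rec, m))

    def record(j: int, X: np.ndarray, y, r, delta_r) -> None:
        R["theta"][j] = X[:, :n]
        R["mu"][j] = X[:, n:2 * n]
        R["rbar"][j] = X[:, i_rbar]
        R["G"][j] = X[:, i_G]
        R["r"][j] = r
        R["delta_r"][j] = delta_r
        R["y"][j] = y
        if d:
            R["z"][j] = X[:, i_aux]
        if meta is not None:
            R["sigma"][j] = X[:, i_sig]
            R["mu_sigma"][j] = X[:, i_musig]

    # periodic environment reset (episodic training): the latent/plant
    # state returns to aux0 while theta, mu, rbar and G carry over
    reset_stride = 0
    if task.reset_interval is not None and d:
        reset_stride = int(round(task.reset_interval / dt))
        if abs(reset_stride * dt - task.reset_interval) > 1e-9 or reset_stride < 1:
            raise ValueError("reset_interval must be a positive multiple of dt")

    noise = np.zeros((m, K))
    for k in range(n_steps):
        if reset_stride and k and k % reset_stride == 0:
            S[:, i_aux] = task.aux0
        if meta is not None:
            noise[:, :n] = S[:, i_sig][:, None] * dW_theta[k]
            noise[:, i_sig] = meta.rho_sigma * dW_sigma[k]
        else:
            noise[:, :n] = sigma_vec * dW_theta[k]
        if dW_env is not None:
            noise[:, i_aux.stop - 1] = system.alpha * dW_env[k, :, 0]
        cache.clear()
        S_next = euler_heun_step(drift, S, times[k], dt, noise)
        if k in rec_pos:
            y1, r1, dr1 = cache[0]
            record(rec_pos[k], S, y1, r1, dr1)
        if meta is not None:
            S_next[:, i_sig] = np.maximum(S_next[:, i_sig], meta.sigma_floor)
        if not np.all(np.isfinite(S_next)):
            bad = _first_nonfinite(S_next, slices)
            raise FloatingPointError(
                f"numerical blow-up in {bad} at t={times[k + 1]:.3f} "
                f"(step {k + 1}, seed base {cfg.seed})"
            )
        S = S_next

    # terminal evaluation at t = T
    cache.clear()
    drift(times[-1], S)
    yT, rT, drT = cache[0]
    record(rec_pos[n_steps], S, yT, rT, drT)

    rec_times = times[rec_idx]
    trajectories = []
    for i in range(m):
        trajectories.append(Trajectory(
            times=rec_times,
            theta_path=R["theta"][:, i, :].copy(),
            mu_path=R["mu"][:, i, :].copy(),
            rbar_path=R["rbar"][:, i].copy(),
            r_path=R["r"][:, i].copy(),
            delta_r_path=R["delta_r"][:, i].copy(),
            G_path=R["G"][:, i].copy(),
            y_path=R["y"][:, i].copy(),
            z_path=R["z"][:, i, :].copy() if d else None,
            sigma_path=R["sigma"][:, i].copy() if meta is not None else None,
            mu_sigma_path=R["mu_sigma"][:, i].copy() if meta is not None else None,
            seed=seeds[i],
        ))
    return Ensemble(trajectories, cfg, hp)


# --------------------------------------------------------------------------
# deployment: freeze theta at mu(T)
# --------------------------------------------------------------------------

@dataclass
class FrozenModel:
    """A model with parameters clamped to the learned mean mu(T).

    Diffusion and mean adaptation are disabled; for static models the
    readout can be applied directly, for dynamic settings use
    :func:`frozen_rollout`.
    """

    model: SystemModel
    theta: np.ndarray

    def predict(self, X: np.ndarray):
        return self.model.readout(self.theta, np.asarray(X, dtype=float))


def freeze_parameters(traj: Trajectory | Ensemble, model: SystemModel) -> FrozenModel:
    """Clamp theta to the final mean parameters mu(T).

    For an :class:`Ensemble`, the per-parameter median of mu(T) across
    trials is used.
    """
    if isinstance(traj, Ensemble):
        if len(traj) == 0:
            raise ValueError("empty ensemble")
        theta = traj.median_mu_T()
    else:
        if traj.mu_path.shape[0] == 0:
            raise ValueError("empty trajectory")
        theta = traj.mu_T
    return FrozenModel(model=model, theta=np.asarray(theta, dtype=float))


def frozen_rollout(
    frozen: FrozenModel,
    task: TaskSpec,
    cfg: IntegratorConfig,
    hp: HyperParams | None = None,
) -> Ensemble:
    """Re-simulate the task with parameters fixed at the frozen values.

    The parameter SDE is disabled (sigma = 0, eta = 0, theta0 = mu0 =
    frozen theta), so for supervised tasks the rollout is fully
    deterministic; control tasks retain their environment noise, which
    is matched across runs at equal seeds because the parameter stream
    is drawn first from each trial's generator.  Periodic environment
    resets are a training device and are disabled for the rollout.
    """
    hp = hp or HyperParams()
    quiet = HyperParams(lam=hp.lam, sigma=0.0, rho=hp.rho, eta=0.0)
    task = dataclasses.replace(
        task, theta0=frozen.theta.copy(), mu0=frozen.theta.copy(),
        reset_interval=None,
    )
    return simulate(frozen.model, task, quiet, cfg)
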