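"""Experiment environments for OU adaptation.

Each task bundles an input signal, a target or reward definition, the
ground-truth parameters (where the task is a recovery problem), the
integration horizon and the initial conditions.  All rewards are
non-positive quadratic costs, so the return G is non-increasing.

Tasks
-----
- ``single_param_task`` / ``multi_sine_task``: supervised recovery of a
  tanh readout driven by (multi-)sinusoidal inputs.
- ``ctrnn_task``: supervised recovery of the three CTRNN weights; the
  target trajectory is produced by a teacher network with fixed
  ground-truth weights, integrated on the same grid.
- ``sdi_task``: stochastic double integrator — a particle with position
  and velocity state, Brownian forcing on the velocity, noisy state
  observations, and a linear feedback agent whose output is the control.
- ``volatile_task``: the single-parameter mapping with a ground truth
  that flips sign mid-run (used by the meta-learning experiment).
- ``weather_task``: 24-step-ahead regression on a synthetic surrogate
  of an hourly weather table (6 correlated features), optionally
  ZCA-whitened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "TaskSpec",
    "SDIParams",
    "SDIState",
    "ZCAWhitener",
    "sine_input",
    "quadratic_reward",
    "sdi_drift",
    "sdi_observe",
    "sdi_reward",
    "volatile_target",
    "zca_whiten",
    "synthetic_weather_generator",
    "load_weather_csv",
    "single_param_task",
    "multi_sine_task",
    "ctrnn_task",
    "sdi_task",
    "volatile_task",
    "weather_task",
    "WEATHER_COLUMNS",
]


# --------------------------------------------------------------------------
# elementary signal / reward definitions
# --------------------------------------------------------------------------

def sine_input(t, i: int, n: int):
    """Component ``i`` of the multi-sine input bank.

    x_i(t) = sin(0.1 * i * t + (i - 1) * 2 pi / n) for 1 <= i <= n:
    distinct frequencies and evenly spread phases per component.  For
    n = 1 this reduces to the canonical slow probe sin(0.1 t).
    """
    if not 1 <= i <= n:
        raise ValueError(f"component index {i} outside 1..{n}")
    t = np.asarray(t, dtype=float)
    return np.sin(0.1 * i * t + (i - 1) * 2.0 * np.pi / n)


def quadratic_reward(y, y_star):
    """Negative squared error ``-(y - y*)^2``; 0 iff the output matches."""
    d = np.asarray(y, dtype=float) - np.asarray(y_star, dtype=float)
    return -(d * d)


def volatile_target(t, t_switch: float):
    """Piecewise-constant ground truth: +1 before the switch, -1 after."""
    t = np.asarray(t, dtype=float)
    return np.where(t < t_switch, 1.0, -1.0)


# --------------------------------------------------------------------------
# stochastic double integrator
# --------------------------------------------------------------------------

@dataclass
class SDIParams:
    """Noise and friction constants of the double integrator.

    alpha: Brownian forcing scale on the velocity; beta: observation
    noise scale; gamma: friction coefficient (1/time).
    """

    alpha: float = 0.005
    beta: float = 0.005
    gamma: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class SDIState:
    """Position/velocity state plus the environment constants."""

    s1: float = 0.0
    s2: float = 0.0
    alpha: float = 0.005
    beta: float = 0.005
    gamma: float = 0.01


def sdi_drift(state: SDIState, y):
    """Drift of (position, velocity): (s2, -gamma*s2 + y).

    The control y enters the acceleration; Brownian forcing (scale
    alpha) applies to the velocity only and is added by the integrator.
    """
    return np.asarray([state.s2, -state.gamma * state.s2 + y], dtype=float)


def sdi_observe(state: SDIState, noise):
    """Noisy state observation ``s + beta * eps`` with eps ~ N(0, I)."""
    noise = np.asarray(noise, dtype=float)
    return np.asarray([state.s1, state.s2], dtype=float) + state.beta * noise


def sdi_reward(state: SDIState, y):
    """Quadratic cost ``-0.5 ||s||^2 - 0.5 y^2`` (set-point at the origin)."""
    return -0.5 * (state.s1**2 + state.s2**2) - 0.5 * float(y) ** 2


# --------------------------------------------------------------------------
# ZCA whitening
# --------------------------------------------------------------------------

@dataclass
class ZCAWhitener:
    """Fitted symmetric (ZCA) whitening transform, reusable on held-out data."""

    mean: np.ndarray
    transform: np.ndarray  # C^{-1/2}, symmetric

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.transform


def zca_whiten(X: np.ndarray, eps: float = 0.0) -> tuple[np.ndarray, ZCAWhitener]:
    """Decorrelate ``X`` with the symmetric inverse square root of its covariance.

    Returns the whitened table (identity covariance up to numerical
    tolerance) and the fitted transform.  ``eps`` regularises the
    eigenvalues; without it a singular covariance raises.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d table with at least two samples")
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    if np.any(evals + eps <= 0):
        raise np.linalg.LinAlgError(
            "singular covariance; pass eps > 0 to regularise"
        )
    W = evecs @ np.diag(1.0 / np.sqrt(evals + eps)) @ evecs.T
    whitener = ZCAWhitener(mean=mean, transform=W)
    return whitener(X), whitener


# --------------------------------------------------------------------------
# synthetic weather surrogate
# --------------------------------------------------------------------------

WEATHER_COLUMNS = [
    "temperature",
    "humidity",
    "wind_speed",
    "wind_dir_sin",
    "wind_dir_cos",
    "pressure",
]

#: Generating coefficients on standardised features: the prediction is
#: dominated by the current temperature, with small contributions from
#: the remaining regressors.
_WEATHER_COEF = np.array([0.85, -0.20, 0.05, 0.03, 0.02, -0.10])
_WEATHER_HORIZON = 24  # steps (hours) ahead


def _ar1(rng: np.random.Generator, n: int, phi: float, scale: float) -> np.ndarray:
    """Stationary AR(1) driver used for slow weather fluctuations."""
    x = np.empty(n)
    innov = rng.standard_normal(n) * scale * np.sqrt(1.0 - phi**2)
    x[0] = rng.standard_normal() * scale
    for k in range(1, n):
        x[k] = phi * x[k - 1] + innov[k]
    return x


def synthetic_weather_generator(
    seed: int,
    n_samples: int,
    noise_scale: float = 0.3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Hourly 6-feature regression surrogate with a 24-step-ahead target.

    Emulates the statistical structure of an hourly weather table:
    seasonal plus diurnal cycles, strong temporal autocorrelation,
    correlated features (humidity anti-correlates with temperature) and
    one dominant predictor.  The target of row ``t`` is a fixed linear
    combination of the *standardised* features at row ``t + 24`` plus
    Gaussian noise, i.e. the quantity a 24 h-ahead forecaster tries to
    predict from the features at row ``t``.

    Returns the table (timestamp, six features, target) and the
    generating coefficients for recovery tests.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 samples")
    rng = np.random.default_rng(seed)
    n = n_samples + _WEATHER_HORIZON
    hours = np.arange(n)
    diurnal = np.sin(2 * np.pi * (hours % 24) / 24.0)
    seasonal = np.sin(2 * np.pi * hours / (24.0 * 365))
    temp = 12.0 + 9.0 * seasonal + 4.0 * diurnal + _ar1(rng, n, 0.98, 2.5)
    humidity = 0.65 - 0.012 * (temp - 12.0) + _ar1(rng, n, 0.95, 0.06)
    humidity = np.clip(humidity, 0.05, 1.0)
    wind = np.abs(3.0 + _ar1(rng, n, 0.9, 1.2))
    angle = np.cumsum(rng.standard_normal(n) * 0.15)
    pressure = 1015.0 + _ar1(rng, n, 0.995, 4.0)
    X = np.column_stack([temp, humidity, wind, np.sin(angle), np.cos(angle), pressure])

    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    future = Z[_WEATHER_HORIZON:]  # features 24 steps ahead of each kept row
    target = future @ _WEATHER_COEF + noise_scale * rng.standard_normal(n_samples)

    df = pd.DataFrame(X[:n_samples], columns=WEATHER_COLUMNS)
    df.insert(0, "timestamp", pd.date_range("2006-01-01", periods=n_samples, freq="h"))
    df["target"] = target
    return df, _WEATHER_COEF.copy()


def load_weather_csv(path, z_thresh: float = 6.0) -> pd.DataFrame:
    """Read a user-supplied hourly weather CSV with the surrogate schema.

    Expects columns ``timestamp`` plus the six feature columns; the
    24 h-ahead temperature target is constructed by shifting.  Outliers
    (beyond ``z_thresh`` robust z-scores) are replaced by linear
    interpolation before any standardisation.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV lacks columns: {missing}")
    for col in WEATHER_COLUMNS:
        x = df[col].astype(float)
        med = x.median()
        mad = (x - med).abs().median()
        scale = 1.4826 * mad if mad > 0 else x.std() or 1.0
        bad = (x - med).abs() > z_thresh * scale
        x[bad] = np.nan
        df[col] = x.interpolate(limit_direction="both")
    df["target"] = df["temperature"].shift(-_WEATHER_HORIZON)
    return df.dropna(subset=["target"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# task specification container + constructors
# --------------------------------------------------------------------------

@dataclass
class TaskSpec:
    """Environment definition consumed by :func:`oua.integrator.simulate`.

    ``input_grid`` maps a time grid (K,) to an input table (K, n_inputs)
    and ``target_grid`` maps (times, inputs) to the target output (K,);
    both are None for the control task, where the agent's input is the
    noisy state observation.  Rewards are non-positive for every task.
    """

    name: str
    n_inputs: int
    T: float
    theta0: np.ndarray
    mu0: np.ndarray
    rbar0: float
    input_grid: Callable[[np.ndarray], np.ndarray] | None = None
    target_grid: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    theta_star: np.ndarray | None = None
    env: SDIParams | None = None
    aux0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_switch: float | None = None
    reset_interval: float | None = None

    def __post_init__(self) -> None:
        if self.reset_interval is not None and self.reset_interval <= 0:
            raise ValueError("reset_interval must be positive or None")
        self.theta0 = np.atleast_1d(np.asarray(self.theta0, dtype=float))
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        if self.theta_star is not None:
            self.theta_star = np.atleast_1d(np.asarray(self.theta_star, dtype=float))
            if not np.all(np.isfinite(self.theta_star)):
                raise ValueError("theta_star must be finite")
        self.aux0 = np.atleast_1d(np.asarray(self.aux0, dtype=float))
        if self.T <= 0:
            raise ValueError("horizon must be positive")


def _multi_sine_grid(n: int) -> Callable[[np.ndarray], np.ndarray]:
    def grid(times: np.ndarray) -> np.ndarray:
        return np.column_stack([sine_input(times, i, n) for i in range(1, n + 1)])

    return grid


def single_param_task(T: float = 1000.0, theta_star: float = 1.0,
                      rbar0: float = -1.0) -> TaskSpec:
    """Recover theta* in y = tanh(theta x) from x(t) = sin(0.1 t)."""
    ts = np.atleast_1d(np.asarray(theta_star, dtype=float))

    def target(times, X):
        return np.tanh(X @ ts)

    return TaskSpec(
        name="single_param",
        n_inputs=1,
        T=T,
        theta0=np.zeros(1),
        mu0=np.zeros(1),
        rbar0=rbar0,
        input_grid=_multi_sine_grid(1),
        target_grid=target,
        theta_star=ts,
    )


def multi_sine_task(
    n: int = 6,
    T: float = 2000.0,
    theta_star=(0.3, 1.1, 0.0, -0.3, -1.5, -0.4),
    rbar0: float = -1.0,
) -> TaskSpec:
    """Recover an n-vector theta* in y = tanh(theta . x) from multi-sine inputs."""
    ts = np.asarray(theta_star, dtype=float)
    if ts.size != n:
        raise ValueError("theta_star length must match n")

    def target(times, X):
        return np.tanh(X @ ts)

    return TaskSpec(
        name="multi_param",
        n_inputs=n,
        T=T,
        theta0=np.zeros(n),
        mu0=np.zeros(n),
        rbar0=rbar0,
        input_grid=_multi_sine_grid(n),
        target_grid=target,
        theta_star=ts,
    )


def _heun_teacher_path(times: np.ndarray, x: np.ndarray, theta_star: np.ndarray,
                       f: Callable, z0: float) -> np.ndarray:
    """Deterministic Heun integration of the teacher CTRNN latent state."""
    th1, th2, _ = theta_star
    z = np.empty_like(times)
    z[0] = z0
    for k in range(times.size - 1):
        dt = times[k + 1] - times[k]
        d1 = f(th1 * z[k] + th2 * x[k]) - z[k]
        zp = z[k] + d1 * dt
        d2 = f(th1 * zp + th2 * x[k + 1]) - zp
        z[k + 1] = z[k] + 0.5 * (d1 + d2) * dt
    return z


def ctrnn_task(
    T: float = 1000.0,
    theta_star=(0.3, 0.7, 1.0),
    theta0=(0.2, 0.1, 0.5),
    rbar0: float = -0.1,
    f: Callable = np.tanh,
    z0: float = 0.0,
) -> TaskSpec:
    """Recover the three CTRNN weights from a 1-D input-output mapping.

    The target output is produced by a teacher network with the fixed
    ground-truth weights, integrated deterministically on the same grid
    and scheme as the student, so a student at theta* earns reward 0.
    """
    ts = np.asarray(theta_star, dtype=float)
    th0 = np.asarray(theta0, dtype=float)

    def target(times, X):
        z = _heun_teacher_path(times, X[:, 0], ts, f, z0)
        return ts[2] * z

    return TaskSpec(
        name="ctrnn",
        n_inputs=1,
        T=T,
        theta0=th0,
        mu0=th0.copy(),
        rbar0=rbar0,
        input_grid=_multi_sine_grid(1),
        target_grid=target,
        theta_star=ts,
        aux0=np.asarray([z0]),
    )


def sdi_task(
    T: float = 2000.0,
    alpha: float = 0.005,
    beta: float = 0.005,
    gamma: float = 0.01,
    rbar0: float = 0.0,
    reset_interval: float | None = 20.0,
) -> TaskSpec:
    """Stabilise the stochastic double integrator with linear state feedback.

    The agent observes the noisy state and outputs the control
    y = theta . (s + beta eps); the optimal feedback gains are negative
    in both components.  All initial conditions are zero.

    Training is episodic by default: every ``reset_interval`` time units
    the plant state is reset to the origin while the learning variables
    (theta, mu, rbar, G) carry over.  Before the gains are learned the
    plant drifts unboundedly (the uncontrolled position variance grows
    like t^3), which drives the reward to large negative values faster
    than the filter can track it; bounding each excursion keeps the
    reward signal in a range where the mean adaptation is informative.
    Set ``reset_interval=None`` for a single uninterrupted episode, as
    used when evaluating a frozen controller.
    """
    return TaskSpec(
        name="sdi",
        n_inputs=2,
        T=T,
        theta0=np.zeros(2),
        mu0=np.zeros(2),
        rbar0=rbar0,
        env=SDIParams(alpha=alpha, beta=beta, gamma=gamma),
        aux0=np.zeros(2),
        reset_interval=reset_interval,
    )


def volatile_task(T: float = 1000.0, t_switch: float | None = None,
                  rbar0: float = 0.0) -> TaskSpec:
    """Single-parameter mapping whose ground truth flips +1 -> -1 mid-run."""
    if t_switch is None:
        t_switch = T / 2.0

    def target(times, X):
        return np.tanh(volatile_target(times, t_switch) * X[:, 0])

    return TaskSpec(
        name="meta_volatile",
        n_inputs=1,
        T=T,
        theta0=np.zeros(1),
        mu0=np.zeros(1),
        rbar0=rbar0,
        input_grid=_multi_sine_grid(1),
        target_grid=target,
        theta_star=np.asarray([-1.0]),  # post-switch truth; +1 before
        t_switch=t_switch,
    )


def weather_task(
    X: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    rbar0: float = 0.0,
    passes: int = 1,
) -> TaskSpec:
    """Continuous-time regression over a (whitened) feature table.

    Row ``k`` of the table is anchored at time ``t = k``; between rows
    the features and target are interpolated with backward-difference
    cubic Hermite splines, and the time axis wraps so the training
    segment can be traversed ``passes`` times.
    """
    from .integrator import CubicHermiteBackward  # local import avoids a cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature table and target disagree in length")
    t_knots = np.arange(X.shape[0], dtype=float)
    span = t_knots[-1]
    interp_x = [CubicHermiteBackward(t_knots, X[:, j]) for j in range(X.shape[1])]
    interp_y = CubicHermiteBackward(t_knots, y)

    def input_grid(times: np.ndarray) -> np.ndarray:
        tw = np.mod(times, span)
        return np.column_stack([f(tw) for f in interp_x])

    def target_grid(times: np.ndarray, _X: np.ndarray) -> np.ndarray:
        return interp_y(np.mod(times, span))

    th0 = np.asarray(theta0, dtype=float)
    return TaskSpec(
        name="weather_surrogate",
        n_inputs=X.shape[1],
        T=span * passes,
        theta0=th0,
        mu0=th0.copy(),
        rbar0=rbar0,
        input_grid=input_grid,
        target_grid=target_grid,
    )
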