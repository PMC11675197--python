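"""Core learning dynamics of Ornstein-Uhlenbeck adaptation (OUA).

OUA casts learning as a stochastic process that co-evolves with
inference.  Each parameter ``theta_i`` follows a mean-reverting
Ornstein-Uhlenbeck (OU) process

    d theta = lam * (mu - theta) dt + sigma dW,

while its mean ``mu_i`` is nudged by a global reward-prediction-error
(RPE) signal

    d mu = eta * delta_r * (theta - mu) dt,

where ``delta_r = r - rbar`` and ``rbar`` is a low-pass filtered
(exponential moving average) estimate of the reward,

    d rbar = rho * (r - rbar) dt.

When a random excursion of ``theta`` raises the reward above its
running average (``delta_r > 0``) the mean chases the excursion;
below-average excursions push the mean away.  No gradients of the model
with respect to its parameters are ever required.

This module holds the update primitives in their explicit-Euler
discretisation plus the small state containers.  The coupled
(Heun-corrected) integration of the full system lives in
:mod:`oua.integrator`.

Because the noise in the OU process is additive, the Ito and
Stratonovich interpretations of the SDE coincide; no correction term is
applied anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LearnerState",
    "HyperParams",
    "RewardSample",
    "reward_filter_step",
    "reward_prediction_error",
    "clipped_rpe",
    "ou_step",
    "mean_step",
    "cumulative_reward_update",
    "stationary_covariance",
]


def _require_finite(**named) -> None:
    for name, value in named.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass
class HyperParams:
    """Fixed-per-run learning hyper-parameters.

    Parameters
    ----------
    lam:
        Mean-reversion rate of the parameter OU process (1/time).
    sigma:
        Diffusion scale; a scalar broadcasts to all parameters
        (``Sigma = sigma * I``), or a per-parameter diagonal.
    rho:
        Reward low-pass filter rate (1/time); ``1/rho`` is the filter
        time constant.
    eta:
        Mean-adaptation learning rate (1/(reward x time)).
    rpe_margin:
        Dimensionless stability margin ``c`` for the mean adaptation.
        The RPE entering the mean update is clipped to ``[-c lam/eta,
        +c lam/eta]``; with ``c < 1`` the theta-mu gap dynamics
        ``d(theta - mu) = -(lam + eta delta_r)(theta - mu) dt + ...``
        stay contractive for every reward signal, because the effective
        repulsion rate ``eta |delta_r|`` can never exceed ``c lam``.
        The default ``inf`` disables clipping (the unmodified rule);
        the reward filter and the return always use the raw RPE.
    """

    lam: float = 1.0
    sigma: float | np.ndarray = 0.3
    rho: float = 1.0
    eta: float = 1.0
    rpe_margin: float = np.inf

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim > 1:
            raise ValueError("sigma must be a scalar or a 1-d diagonal")
        _require_finite(lam=self.lam, sigma=self.sigma, rho=self.rho, eta=self.eta)
        if self.lam < 0 or self.rho < 0 or self.eta < 0 or np.any(self.sigma < 0):
            raise ValueError("hyper-parameters must be non-negative")
        if not self.rpe_margin > 0:
            raise ValueError("rpe_margin must be positive (inf disables clipping)")

    def rpe_bound(self) -> float:
        """Absolute clip bound ``rpe_margin * lam / eta`` for the mean update."""
        if not np.isfinite(self.rpe_margin) or self.eta == 0:
            return np.inf
        return self.rpe_margin * self.lam / self.eta

    def sigma_vector(self, n: int) -> np.ndarray:
        """Per-parameter diffusion diagonal of length ``n``."""
        sig = np.atleast_1d(self.sigma)
        if sig.size == 1:
            return np.full(n, float(sig[0]))
        if sig.size != n:
            raise ValueError(f"sigma has length {sig.size}, expected 1 or {n}")
        return sig.astype(float)


@dataclass
class LearnerState:
    """The co-evolving learning variables (theta, mu, rbar, G)."""

    theta: np.ndarray
    mu: np.ndarray
    rbar: float
    G: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if self.theta.shape != self.mu.shape:
            raise ValueError(
                f"theta and mu must share a shape, got {self.theta.shape} vs {self.mu.shape}"
            )
        if self.theta.size < 1:
            raise ValueError("need at least one parameter")
        _require_finite(theta=self.theta, mu=self.mu, rbar=self.rbar, G=self.G)

    @property
    def n(self) -> int:
        return self.theta.size


@dataclass
class RewardSample:
    """Instantaneous reward and the RPE computed against a given rbar."""

    r: float
    delta_r: float


def reward_filter_step(rbar, r, rho: float, dt: float):
    """One explicit-Euler step of the reward low-pass filter.

    Returns ``rbar + rho * (r - rbar) * dt``, the discretisation of
    ``d rbar = rho (r - rbar) dt``.  ``rho = 0`` freezes the estimate.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    _require_finite(rbar=rbar, r=r)
    return rbar + rho * (r - rbar) * dt


def reward_prediction_error(r, rbar):
    """The RPE ``delta_r = r - rbar``."""
    _require_finite(r=r, rbar=rbar)
    return r - rbar


def ou_step(
    theta: np.ndarray,
    mu: np.ndarray,
    lam: float,
    sigma,
    dt: float,
    dW: np.ndarray,
) -> np.ndarray:
    """One Euler-Maruyama step of the parameter OU process.

    ``dW`` is a caller-supplied Wiener increment vector (mean 0,
    variance ``dt`` per component).  Drift and noise enter additively:

        theta + lam * (mu - theta) * dt + sigma * dW
    """
    theta = np.asarray(theta, dtype=float)
    mu = np.asarray(mu, dtype=float)
    dW = np.asarray(dW, dtype=float)
    if theta.shape != mu.shape or theta.shape != dW.shape:
        raise ValueError(
            f"shape mismatch: theta {theta.shape}, mu {mu.shape}, dW {dW.shape}"
        )
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 1 and sigma.size not in (1, theta.size):
        raise ValueError(f"sigma length {sigma.size} incompatible with n={theta.size}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return theta + lam * (mu - theta) * dt + sigma * dW


def clipped_rpe(delta_r, bound: float):
    """RPE clipped to ``[-bound, +bound]`` for use in the mean update.

    With ``bound = c * lam / eta`` and ``c < 1`` the mean adaptation can
    never repel the mean faster than the OU process reverts toward it,
    which makes the theta-mu gap dynamics contractive for any reward
    signal.  ``bound = inf`` returns the RPE unchanged.
    """
    if not bound > 0:
        raise ValueError("bound must be positive")
    if not np.isfinite(bound):
        return delta_r
    return np.clip(delta_r, -bound, bound)


def mean_step(
    mu: np.ndarray,
    theta: np.ndarray,
    eta: float,
    delta_r: float,
    dt: float,
) -> np.ndarray:
    """One Euler step of the RPE-modulated mean adaptation.

    Returns ``mu + eta * delta_r * (theta - mu) * dt``: a positive RPE
    moves the mean toward the currently perturbed parameter, a negative
    RPE moves it away.  Callers that enable the stability margin clip
    ``delta_r`` with :func:`clipped_rpe` before passing it in.
    """
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if mu.shape != theta.shape:
        raise ValueError(f"shape mismatch: mu {mu.shape}, theta {theta.shape}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return mu + eta * delta_r * (theta - mu) * dt


def cumulative_reward_update(G, r, dt: float):
    """Rectangle-rule update of the return: ``G + r * dt``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    _require_finite(G=G, r=r)
    return G + r * dt


def stationary_covariance(sigma, lam: float):
    """Stationary per-parameter variance of the OU process, sigma^2 / (2 lam).

    With the mean frozen, theta is asymptotically Gaussian around mu
    with this variance; it quantifies the residual exploration spread
    after convergence.
    """
    if lam <= 0:
        raise ValueError("no stationary law for lam <= 0")
    sigma = np.asarray(sigma, dtype=float)
    _require_finite(sigma=sigma, lam=lam)
    out = sigma**2 / (2.0 * lam)
    return float(out) if out.ndim == 0 else out
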