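"""Parametric inference models trained by OU adaptation.

Three model families cover the experiments: a bounded static readout
``y = tanh(theta . x)``, an unbounded linear readout ``y = theta . x``
(regression and control), and a one-unit continuous-time recurrent
network (CTRNN / latent ODE)

    dz = (f(theta1 z + theta2 x) - z) dt,    y = theta3 z,

with ``f`` a saturating nonlinearity (tanh by default).  All functions
broadcast over a leading trial axis so ensembles integrate vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SystemModel",
    "tanh_readout",
    "linear_readout",
    "ctrnn_drift",
    "ctrnn_output",
]

STATIC_TANH = "static_tanh"
STATIC_LINEAR = "static_linear"
CTRNN = "ctrnn"


@dataclass
class SystemModel:
    """Configuration of the inference map (g_theta, f_theta).

    ``static_*`` models have no latent state; the CTRNN carries a
    one-dimensional latent state with deterministic drift (process
    noise is not injected into the latent equation) and three
    parameters: recurrent weight, input weight, output weight.
    """

    kind: str
    n_params: int
    latent_dim: int = 0
    nonlinearity: Callable[[np.ndarray], np.ndarray] = field(default=np.tanh)
    z0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (STATIC_TANH, STATIC_LINEAR, CTRNN):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == CTRNN:
            if self.n_params != 3 or self.latent_dim != 1:
                raise ValueError("ctrnn uses n_params=3 and latent_dim=1")
        elif self.latent_dim != 0:
            raise ValueError("static models have no latent state")

    @classmethod
    def static_tanh(cls, n_params: int) -> "SystemModel":
        return cls(kind=STATIC_TANH, n_params=n_params)

    @classmethod
    def static_linear(cls, n_params: int) -> "SystemModel":
        return cls(kind=STATIC_LINEAR, n_params=n_params)

    @classmethod
    def ctrnn(cls, nonlinearity=np.tanh, z0: float = 0.0) -> "SystemModel":
        return cls(kind=CTRNN, n_params=3, latent_dim=1,
                   nonlinearity=nonlinearity, z0=z0)

    def readout(self, theta: np.ndarray, x: np.ndarray):
        """Static output map; not defined for the recurrent model."""
        if self.kind == STATIC_TANH:
            return tanh_readout(theta, x)
        if self.kind == STATIC_LINEAR:
            return linear_readout(theta, x)
        raise ValueError("recurrent models need a latent state; use ctrnn_output")


def _check_lengths(theta: np.ndarray, x: np.ndarray) -> None:
    if theta.shape[-1] != x.shape[-1]:
        raise ValueError(
            f"theta and x must share their last dimension, got "
            f"{theta.shape[-1]} vs {x.shape[-1]}"
        )


def tanh_readout(theta, x):
    """Bounded readout ``tanh(theta . x)``, output in (-1, 1)."""
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    _check_lengths(np.atleast_1d(theta), np.atleast_1d(x))
    return np.tanh(np.sum(theta * x, axis=-1))


def linear_readout(theta, x):
    """Linear readout ``theta . x``."""
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    _check_lengths(np.atleast_1d(theta), np.atleast_1d(x))
    return np.sum(theta * x, axis=-1)


def ctrnn_drift(z, x, theta1, theta2, f: Callable = np.tanh):
    """Latent drift ``f(theta1 z + theta2 x) - z`` of the one-unit CTRNN.

    For ``f`` saturating at 1 the drift is negative whenever ``|z| > 1``,
    so the latent state stays bounded.
    """
    return f(theta1 * z + theta2 * x) - z


def ctrnn_output(z, theta3):
    """Linear CTRNN readout ``theta3 * z``."""
    return theta3 * z
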