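"""Synthetic oracle systems with known answers.

The saddle-node normal form ``x' = a - x**2`` has its fold exactly at
``a = 0`` and, perturbed into the basin of the stable root ``+sqrt(a)``,
a maximal recovery rate of exactly ``a`` (attained at ``x = 0``), i.e.
``a * dt`` per Euler step.  That makes it an exact end-to-end oracle for
the perturbation-recovery estimator.  An AR(1) generator provides series
with known autocorrelation, variance and spectrum for the indicator
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SimulationDivergedError
from .trajectory import Trajectory

__all__ = [
    "NormalFormConfig",
    "simulate_saddle_normal_form",
    "simulate_ar1",
    "NormalFormRecoveryModel",
]


@dataclass
class NormalFormConfig:
    """Euler discretization of ``x' = a - x**2`` with optional noise."""

    a: float
    dt: float = 0.01
    n_steps: int = 1000
    x0: float = 0.0
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def simulate_saddle_normal_form(cfg: NormalFormConfig) -> Trajectory:
    """Iterate ``x_{t+1} = x_t + (a - x_t**2) dt + sigma N_t``.

    Trajectories that leave the basin of ``+sqrt(a)`` run off to minus
    infinity in finite time; that divergence raises
    :class:`SimulationDivergedError`.
    """
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(cfg.n_steps) if cfg.sigma > 0 else np.zeros(cfg.n_steps)
    bound = 10.0 * max(1.0, math.sqrt(abs(cfg.a)))
    values = np.empty(cfg.n_steps + 1)
    x = float(cfg.x0)
    values[0] = x
    for t in range(cfg.n_steps):
        x = x + (cfg.a - x * x) * cfg.dt + cfg.sigma * noise[t]
        if not -bound < x < bound:
            raise SimulationDivergedError(
                f"normal form diverged at step {t + 1} (a={cfg.a:g})"
            )
        values[t + 1] = x
    return Trajectory(values, dt=cfg.dt, parameter_name="a",
                      parameter_values=cfg.a, seed=cfg.seed)


def simulate_ar1(phi: float, sigma: float, n: int, seed: int | None = None) -> np.ndarray:
    """AR(1) series ``x_t = phi x_{t-1} + sigma e_t`` from a stationary start."""
    if not -1.0 < phi < 1.0:
        raise ValueError("phi must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x0 = rng.normal(0.0, sigma / math.sqrt(1.0 - phi * phi)) if sigma > 0 else 0.0
    eps = rng.standard_normal(n) * sigma
    prev = x0
    for t in range(n):
        prev = phi * prev + eps[t]
        x[t] = prev
    return x


class NormalFormRecoveryModel:
    """Recovery-model backend for the saddle-node normal form.

    The swept parameter is ``a``; the initial (equilibrium) state is
    ``+sqrt(a)`` and the default perturbation places the state at
    ``x0_factor * sqrt(a)`` -- inside the basin, above the unstable root
    ``-sqrt(a)``, with enough margin that additive noise does not eject
    realizations across it.
    """

    def __init__(self, dt: float = 0.01, sigma: float = 0.0,
                 x0_factor: float = -0.6):
        if not -1.0 < x0_factor:
            raise ValueError("x0_factor must exceed -1 (inside the basin)")
        self.dt = dt
        self.sigma = sigma
        self.x0_factor = x0_factor

    def initial_state(self, c: float, rng: np.random.Generator) -> float:
        if c <= 0:
            raise ValueError("recovery experiments need a > 0")
        return math.sqrt(c)

    def advance(self, state, n_steps, c, rng):
        noise = rng.standard_normal(n_steps) if self.sigma > 0 else np.zeros(n_steps)
        bound = 10.0 * max(1.0, math.sqrt(c))
        values = np.empty(n_steps)
        x = state
        for t in range(n_steps):
            x = x + (c - x * x) * self.dt + self.sigma * noise[t]
            if not -bound < x < bound:
                raise SimulationDivergedError(f"normal form diverged (a={c:g})")
            values[t] = x
        return values, x

    def perturb(self, state, spec, c, rng):
        if callable(spec.amplitude):
            return float(spec.amplitude(c))
        if spec.amplitude is not None:
            return float(spec.amplitude)
        return self.x0_factor * math.sqrt(c)

    def observe(self, state) -> float:
        return float(state)
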