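"""Mean-field (equation-based) Ising model.

The aggregate magnetization ``M`` evolves by the Euler-discretized
self-consistency dynamics

    M_{t+1} = M_t + (-M_t + tanh(c * M_t + H)) * dt + sigma * N_t,

where ``N_t`` are i.i.d. standard-normal draws added with weight ``sigma``
(no sqrt(dt) scaling: the noise weight is defined per time-step, which is
the convention the sigma = 0.01 calibration refers to).  The coupling ``c``
in the tanh argument defaults to the temperature ``T``; it is exposed as a
separate parameter because the effective coupling is the natural handle for
matching the mean-field bistable window to the lattice model (see
:func:`isingcsd.experiments.calibrate_coupling`).

Deterministic structure (sigma = 0):

* equilibria are the roots of ``M = tanh(c*M + H)``;
* for ``c > 1`` the model is bistable for ``|H|`` below the fold field
  ``w(c) = c*sqrt(1 - 1/c) - arccosh(sqrt(c))``, a pair of saddle-node
  bifurcations producing hysteresis;
* at ``H = 0`` the symmetric pair of ordered states appears in a
  supercritical pitchfork at ``c = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect, brentq

from .errors import NoBistableRegionError, SimulationDivergedError
from .trajectory import Trajectory

__all__ = [
    "MeanFieldConfig",
    "EquilibriumBranch",
    "step_meanfield",
    "simulate_meanfield",
    "meanfield_equilibria",
    "fold_points",
    "coupling_for_fold",
    "equilibrium_curves",
]

#: divergence guard for the simulated state
_STATE_BOUND = 1e6


@dataclass
class MeanFieldConfig:
    """Configuration of one mean-field simulation.

    ``temperature`` and ``external_field`` may each be a scalar or a
    per-step schedule of length ``n_steps`` (a ramp for sweep experiments).
    ``coupling`` overrides the tanh-argument multiplier; ``None`` means
    "use the temperature", the printed form of the model.
    """

    temperature: float | np.ndarray = 2.12
    external_field: float | np.ndarray = 0.0
    dt: float = 0.1
    sigma: float = 0.0
    n_steps: int = 1000
    m0: float = 0.0
    seed: int | None = None
    coupling: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if not -1.5 <= self.m0 <= 1.5:
            raise ValueError("m0 must lie in [-1.5, 1.5]")

    def _schedule(self, value: float | np.ndarray) -> np.ndarray:
        if np.ndim(value) == 0:
            return np.full(self.n_steps, float(value))
        arr = np.asarray(value, dtype=float)
        if len(arr) != self.n_steps:
            raise ValueError("parameter schedule must have length n_steps")
        return arr

    def coupling_schedule(self) -> np.ndarray:
        source = self.temperature if self.coupling is None else self.coupling
        return self._schedule(source)

    def field_schedule(self) -> np.ndarray:
        return self._schedule(self.external_field)


def step_meanfield(m: float, cfg: MeanFieldConfig, noise_draw: float, step: int = 0) -> float:
    """One Euler update of the magnetization.

    ``noise_draw`` is a standard-normal variate (pass 0 for sigma = 0);
    ``step`` selects the schedule entry when parameters are ramped.
    """
    c = cfg.coupling_schedule()[step]
    h = cfg.field_schedule()[step]
    return m + (-m + math.tanh(c * m + h)) * cfg.dt + cfg.sigma * noise_draw


def simulate_meanfield(cfg: MeanFieldConfig) -> Trajectory:
    """Simulate the mean-field model; returns ``n_steps + 1`` states.

    Reproducible given ``cfg.seed``.  Raises
    :class:`SimulationDivergedError` if the state leaves the finite range
    (a diagnostic for divergent parameters).
    """
    coupling = cfg.coupling_schedule()
    field = cfg.field_schedule()
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(cfg.n_steps) if cfg.sigma > 0 else np.zeros(cfg.n_steps)

    values = np.empty(cfg.n_steps + 1)
    m = float(cfg.m0)
    values[0] = m
    dt = cfg.dt
    sigma = cfg.sigma
    tanh = math.tanh
    for t in range(cfg.n_steps):
        m = m + (-m + tanh(coupling[t] * m + field[t])) * dt + sigma * noise[t]
        if not -_STATE_BOUND < m < _STATE_BOUND:
            raise SimulationDivergedError(
                f"state non-finite at step {t + 1} (c={coupling[t]:g}, H={field[t]:g})"
            )
        values[t + 1] = m

    swept = "T" if np.ndim(cfg.temperature) else "H"
    params = cfg.temperature if swept == "T" else cfg.external_field
    if np.ndim(params):
        params = np.concatenate([[params[0]], np.asarray(params, dtype=float)])
    return Trajectory(values, dt=cfg.dt, parameter_name=swept,
                      parameter_values=params, seed=cfg.seed)


def _self_consistency(m: float, coupling: float, field: float) -> float:
    return m - math.tanh(coupling * m + field)


def _is_stable(m: float, coupling: float, field: float) -> bool:
    sech2 = 1.0 / math.cosh(coupling * m + field) ** 2
    return -1.0 + coupling * sech2 < 0.0


def meanfield_equilibria(
    T: float, H: float, coupling: float | None = None
) -> list[tuple[float, str]]:
    """All real roots of ``M = tanh(c*M + H)`` with stability labels.

    Roots are bracketed by dense sign changes on [-1, 1] (step 1e-3) and
    refined by bisection; each root satisfies the defining equation to
    better than 1e-9.  Returns 1 or 3 ``(root, "stable"|"unstable")``
    pairs sorted by the root value.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    c = T if coupling is None else coupling
    grid = np.linspace(-1.0, 1.0, 2001)
    f = grid - np.tanh(c * grid + H)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = f[i], f[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(bisect(_self_consistency, grid[i], grid[i + 1],
                                args=(c, H), xtol=1e-13))
    if f[-1] == 0.0:
        roots.append(grid[-1])
    # collapse near-degenerate brackets (double roots exactly at a fold)
    deduped: list[float] = []
    for r in roots:
        if not deduped or abs(r - deduped[-1]) > 1e-6:
            deduped.append(r)
    return [(r, "stable" if _is_stable(r, c, H) else "unstable") for r in deduped]


def _fold_width(coupling: float) -> float:
    return coupling * math.sqrt(1.0 - 1.0 / coupling) - math.acosh(math.sqrt(coupling))


def fold_points(T: float, coupling: float | None = None) -> tuple[float, float]:
    """Field values of the two saddle-node folds, ``(H_lower, H_upper)``.

    Closed form: the folds sit where the stable and unstable roots collide,
    at ``|H| = c*sqrt(1 - 1/c) - arccosh(sqrt(c))``, symmetric about H = 0.
    Requires ``c > 1`` (otherwise there is no bistable region).
    """
    c = T if coupling is None else coupling
    if c <= 1.0:
        raise NoBistableRegionError(f"no bistable region for coupling {c:g} <= 1")
    w = _fold_width(c)
    return (-w, w)


def coupling_for_fold(width: float, bracket: tuple[float, float] = (1.0 + 1e-9, 10.0)) -> float:
    """Invert the fold closed form: the coupling whose fold field is ``width``."""
    if width <= 0:
        raise ValueError("fold width must be positive")
    return brentq(lambda c: _fold_width(c) - width, *bracket)


@dataclass
class EquilibriumBranch:
    """One continuous branch of equilibria over a parameter grid."""

    parameter: np.ndarray
    state: np.ndarray
    stability: np.ndarray  # "stable" | "unstable" per point

    def __len__(self) -> int:
        return len(self.parameter)


def equilibrium_curves(
    T: float,
    parameter_grid: np.ndarray,
    coupling: float | None = None,
) -> list[EquilibriumBranch]:
    """Equilibria of the mean-field model over a sorted field grid.

    Points are assembled into continuous branches (adjacent states on one
    branch differ by less than 0.1), suitable for overplotting against
    simulation sweeps.  Stability flags flip only at fold points.
    """
    grid = np.asarray(parameter_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("parameter grid must be a non-empty 1-D array")
    open_branches: list[dict] = []
    closed: list[dict] = []
    for h in grid:
        eq = meanfield_equilibria(T, h, coupling=coupling)
        unmatched = list(eq)
        still_open = []
        for br in open_branches:
            best, best_d = None, 0.1
            for cand in unmatched:
                d = abs(cand[0] - br["state"][-1])
                if d < best_d:
                    best, best_d = cand, d
            if best is not None:
                unmatched.remove(best)
                br["parameter"].append(h)
                br["state"].append(best[0])
                br["stability"].append(best[1])
                still_open.append(br)
            else:
                closed.append(br)
        open_branches = still_open
        for root, stab in unmatched:
            open_branches.append(
                {"parameter": [h], "state": [root], "stability": [stab]}
            )
    closed.extend(open_branches)
    return [
        EquilibriumBranch(
            np.array(br["parameter"]),
            np.array(br["state"]),
            np.array(br["stability"]),
        )
        for br in closed
    ]
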