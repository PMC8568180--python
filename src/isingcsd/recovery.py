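"""Perturbation-recovery experiments.

The critical-slowing-down estimator needs, for each value ``c`` of the
critical parameter, the ensemble-averaged trajectory of the system after a
one-time-step perturbation applied at the end of a transient.  This module
runs those experiments against any backend implementing the small
:class:`RecoveryModel` protocol (mean-field, lattice, or the saddle-node
normal form used as a test oracle).

Protocol per realization:

1. simulate ``transient`` steps at fixed ``c`` from the model's initial
   state;
2. take the equilibrium reference as the mean over the last 20% of the
   transient window;
3. apply the perturbation for one time step (mean-field: set the state to
   the amplitude; lattice: redraw every spin with alignment probability
   ``r`` toward the current equilibrium sign);
4. record ``recovery_length`` further steps.

Realizations are averaged into a single mean recovery curve (the object
the estimator differences); per-realization analysis is deliberately not
offered.  An ensemble mean that never re-enters the 5% band around the
equilibrium reference is flagged with a warning, not an exception, so
near-bifurcation sweeps can be explored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import SimulationDivergedError

__all__ = [
    "PerturbationSpec",
    "RecoveryCurve",
    "RecoveryModel",
    "MeanFieldRecoveryModel",
    "LatticeRecoveryModel",
    "run_recovery",
    "run_experiment",
]

#: fraction of the transient window used for the equilibrium reference
_EQ_FRACTION = 0.2
#: re-entry band, as a fraction of the initial displacement
_RECOVERY_BAND = 0.05


@dataclass
class PerturbationSpec:
    """Specification of one perturbation-recovery experiment.

    ``parameter_values`` are the critical-parameter values ``c_1..c_k``
    (at least two, sorted ascending).  ``amplitude`` applies to the
    ``ebm_state_set`` mode and may be a number or a callable ``c -> value``;
    ``alignment_r`` applies to ``abm_alignment_reset``.
    """

    parameter_values: Sequence[float]
    parameter_name: str = "H"
    mode: str = "ebm_state_set"
    amplitude: float | None = 1.5
    alignment_r: float = 0.0
    transient: int = 100
    recovery_length: int = 400
    realizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        values = [float(v) for v in self.parameter_values]
        if len(values) < 2:
            raise ValueError("need at least two perturbation parameter values")
        if sorted(values) != values:
            raise ValueError("parameter_values must be sorted ascending")
        if self.mode not in ("ebm_state_set", "abm_alignment_reset"):
            raise ValueError("unknown perturbation mode")
        if not 0.0 <= self.alignment_r <= 1.0:
            raise ValueError("alignment_r must lie in [0, 1]")
        if self.transient < 1:
            raise ValueError("transient must be at least 1 step")
        if self.realizations < 1:
            raise ValueError("need at least one realization")
        self.parameter_values = values


@dataclass
class RecoveryCurve:
    """Ensemble-averaged post-perturbation trajectory at one parameter value.

    ``mean[0]`` is the perturbed state; ``sd`` is the per-step ensemble
    standard deviation; ``y_eq`` the pre-perturbation equilibrium
    reference (ensemble mean over the late transient).
    """

    c: float
    mean: np.ndarray
    sd: np.ndarray
    y_eq: float
    n_realizations: int
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mean)


@runtime_checkable
class RecoveryModel(Protocol):
    """Minimal backend interface for perturbation-recovery runs."""

    def initial_state(self, c: float, rng: np.random.Generator): ...

    def advance(self, state, n_steps: int, c: float, rng: np.random.Generator):
        """Advance ``n_steps``; return ``(values, new_state)`` where
        ``values`` are the ``n_steps`` post-update observations."""

    def perturb(self, state, spec: PerturbationSpec, c: float,
                rng: np.random.Generator): ...

    def observe(self, state) -> float: ...


class MeanFieldRecoveryModel:
    """Mean-field backend; the swept parameter is ``H`` or ``T``."""

    def __init__(self, temperature: float = 2.12, dt: float = 0.1,
                 sigma: float = 0.01, coupling: float | None = None,
                 swept: str = "H", fixed_field: float = 0.0, m0: float = -1.0):
        if swept not in ("H", "T"):
            raise ValueError("swept must be 'H' or 'T'")
        self.temperature = temperature
        self.dt = dt
        self.sigma = sigma
        self.coupling = coupling
        self.swept = swept
        self.fixed_field = fixed_field
        self.m0 = m0

    def _params(self, c: float) -> tuple[float, float]:
        if self.swept == "H":
            coupling = self.temperature if self.coupling is None else self.coupling
            return coupling, c
        coupling = c if self.coupling is None else self.coupling
        return coupling, self.fixed_field

    def initial_state(self, c: float, rng: np.random.Generator) -> float:
        return float(self.m0)

    def advance(self, state, n_steps, c, rng):
        import math

        coupling, h = self._params(c)
        noise = rng.standard_normal(n_steps) if self.sigma > 0 else np.zeros(n_steps)
        values = np.empty(n_steps)
        m = state
        dt, sigma = self.dt, self.sigma
        for t in range(n_steps):
            m = m + (-m + math.tanh(coupling * m + h)) * dt + sigma * noise[t]
            values[t] = m
        if not np.isfinite(m):
            raise SimulationDivergedError(f"mean-field state diverged at c={c:g}")
        return values, m

    def perturb(self, state, spec, c, rng):
        amp = spec.amplitude(c) if callable(spec.amplitude) else spec.amplitude
        if amp is None:
            raise ValueError("ebm_state_set perturbation needs an amplitude")
        return float(amp)

    def observe(self, state) -> float:
        return float(state)


class LatticeRecoveryModel:
    """Lattice backend; one time step is one Metropolis sweep."""

    def __init__(self, L: int = 100, temperature: float = 2.12,
                 swept: str = "H", fixed_field: float = 0.0, init: str = "down",
                 reference_sign: int | None = None):
        if swept not in ("H", "T"):
            raise ValueError("swept must be 'H' or 'T'")
        self.L = L
        self.temperature = temperature
        self.swept = swept
        self.fixed_field = fixed_field
        self.init = init
        self.reference_sign = reference_sign

    def _params(self, c: float) -> tuple[float, float]:
        if self.swept == "H":
            return self.temperature, c
        return c, self.fixed_field

    def initial_state(self, c, rng):
        from .lattice import random_lattice

        return random_lattice(self.L, rng, self.init)

    def advance(self, state, n_steps, c, rng):
        from .lattice import _attempts, magnetization

        T, h = self._params(c)
        values = np.empty(n_steps)
        L2 = self.L * self.L
        for t in range(n_steps):
            si = rng.integers(0, self.L, size=L2)
            sj = rng.integers(0, self.L, size=L2)
            u = rng.random(L2)
            _attempts(state, float(T), float(h), si, sj, u)
            values[t] = magnetization(state)
        return values, state

    def perturb(self, state, spec, c, rng):
        from .lattice import magnetization, perturb_alignment

        if self.reference_sign is not None:
            sign = self.reference_sign
        else:
            sign = -1 if magnetization(state) < 0 else 1
        return perturb_alignment(state, spec.alignment_r, rng, sign)

    def observe(self, state) -> float:
        from .lattice import magnetization

        return magnetization(state)


def run_recovery(
    model: RecoveryModel,
    spec: PerturbationSpec,
    c: float,
    seed: int | np.random.SeedSequence | None = None,
) -> RecoveryCurve:
    """Run the ensemble of perturbation-recovery realizations at one ``c``.

    Realizations receive independent child streams of the given seed (the
    spec's base seed when none is passed).  Divergent realizations are
    dropped with a warning; at least half the ensemble must survive.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = ss.spawn(spec.realizations)

    curves = []
    yeqs = []
    warnings: list[str] = []
    n_eq = max(1, int(_EQ_FRACTION * spec.transient))
    for child in children:
        rng = np.random.default_rng(child)
        try:
            state = model.initial_state(c, rng)
            transient_values, state = model.advance(state, spec.transient, c, rng)
            y_eq_r = float(np.mean(transient_values[-n_eq:]))
            state = model.perturb(state, spec, c, rng)
            curve = np.empty(spec.recovery_length + 1)
            curve[0] = model.observe(state)
            curve[1:], state = model.advance(state, spec.recovery_length, c, rng)
        except SimulationDivergedError:
            continue
        curves.append(curve)
        yeqs.append(y_eq_r)

    dropped = spec.realizations - len(curves)
    if dropped:
        warnings.append(f"{dropped} divergent realization(s) dropped")
    if len(curves) < max(1, spec.realizations // 2):
        raise SimulationDivergedError(
            f"more than half the ensemble diverged at c={c:g}"
        )

    stack = np.asarray(curves)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    y_eq = float(np.mean(yeqs))

    band = _RECOVERY_BAND * abs(mean[0] - y_eq)
    if not np.any(np.abs(mean - y_eq) <= band):
        warnings.append("non-recovery: ensemble mean never re-entered the "
                        f"{_RECOVERY_BAND:.0%} band around y_eq")
    return RecoveryCurve(
        c=float(c), mean=mean, sd=sd, y_eq=y_eq,
        n_realizations=len(curves), warnings=warnings,
    )


def run_experiment(model: RecoveryModel, spec: PerturbationSpec) -> list[RecoveryCurve]:
    """One :class:`RecoveryCurve` per parameter value, independent seeds.

    Curves are returned in the (sorted) order of ``spec.parameter_values``;
    per-curve warnings propagate on the curves themselves.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.parameter_values))
    return [
        run_recovery(model, spec, c, seed=child)
        for c, child in zip(spec.parameter_values, children)
    ]
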