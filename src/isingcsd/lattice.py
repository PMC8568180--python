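"""2D lattice (agent-based) Ising model with Metropolis dynamics.

Spins ``S in {-1, +1}`` sit on an L x L grid with periodic boundaries and
interact in a von Neumann neighborhood.  A single update attempt picks a
site uniformly at random, computes the energy a flip would cost,

    Ediff = 2 * S * (NB - H),

with ``NB`` the sum of the four neighbor spins, and flips the spin if
``Ediff <= 0`` or with probability ``exp(-Ediff / T)`` otherwise.  One
sweep is ``L**2`` such attempts and is the model's unit time step.

Note the printed sign convention: the external field enters as ``-H``, so
positive ``H`` favours spin -1.  All experiment code in this package keeps
that convention and handles the sign flip relative to the mean-field model
(where positive ``H`` favours positive magnetization) explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .trajectory import Trajectory

__all__ = [
    "LatticeConfig",
    "SiteProbabilityTrace",
    "random_lattice",
    "neighbor_sum",
    "energy_diff",
    "flip_decision",
    "metropolis_sweep",
    "magnetization",
    "perturb_alignment",
    "simulate_lattice",
    "hysteresis_loop",
    "transition_field",
    "site_state_probability",
]


@dataclass
class LatticeConfig:
    """Configuration of one lattice simulation.

    ``field_schedule`` is a constant or a per-sweep array (a linear ramp
    for sweep experiments); ``temperature`` likewise.  Magnetization is
    recorded every ``record_every`` sweeps.  ``init`` is one of ``"up"``,
    ``"down"``, ``"random"`` (i.i.d. fair-coin spins, the default).
    """

    L: int = 100
    temperature: float | np.ndarray = 2.12
    field_schedule: float | np.ndarray = 0.0
    sweeps: int = 100
    record_every: int = 1
    seed: int | None = None
    init: str = "random"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be at least 2")
        if self.sweeps < 1:
            raise ValueError("sweeps must be at least 1")
        if self.record_every < 1:
            raise ValueError("record_every must be at least 1")
        if self.init not in ("up", "down", "random"):
            raise ValueError("init must be 'up', 'down' or 'random'")

    def _schedule(self, value) -> np.ndarray:
        if np.ndim(value) == 0:
            return np.full(self.sweeps, float(value))
        arr = np.asarray(value, dtype=float)
        if len(arr) != self.sweeps:
            raise ValueError("per-sweep schedule must have length sweeps")
        return arr


def random_lattice(L: int, rng: np.random.Generator, init: str = "random") -> np.ndarray:
    """A fresh L x L spin grid (int8, values in {-1, +1})."""
    if init == "up":
        return np.ones((L, L), dtype=np.int8)
    if init == "down":
        return -np.ones((L, L), dtype=np.int8)
    return rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L))


def neighbor_sum(spins: np.ndarray, i: int, j: int) -> int:
    """Sum of the four von Neumann neighbors with periodic wrap-around."""
    L = spins.shape[0]
    if not (0 <= i < L and 0 <= j < L):
        raise IndexError(f"site ({i}, {j}) outside a {L}x{L} lattice")
    return int(
        spins[(i + 1) % L, j]
        + spins[(i - 1) % L, j]
        + spins[i, (j + 1) % L]
        + spins[i, (j - 1) % L]
    )


def energy_diff(S: int, NB: int, H: float) -> float:
    """Energy cost of flipping spin ``S`` given neighbor sum ``NB``."""
    return 2.0 * S * (NB - H)


def flip_decision(Ediff: float, T: float, p: float) -> bool:
    """Metropolis acceptance: always accept downhill, else ``p < exp(-Ediff/T)``."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return Ediff <= 0 or p < np.exp(-Ediff / T)


@njit(cache=True)
def _attempts(spins, T, H, sites_i, sites_j, uniforms):  # pragma: no cover - jitted
    L = spins.shape[0]
    for k in range(sites_i.shape[0]):
        i = sites_i[k]
        j = sites_j[k]
        nb = (
            spins[(i + 1) % L, j]
            + spins[(i - 1) % L, j]
            + spins[i, (j + 1) % L]
            + spins[i, (j - 1) % L]
        )
        ediff = 2.0 * spins[i, j] * (nb - H)
        if ediff <= 0.0 or uniforms[k] < np.exp(-ediff / T):
            spins[i, j] = -spins[i, j]


def metropolis_sweep(
    spins: np.ndarray, T: float, H: float, rng: np.random.Generator
) -> np.ndarray:
    """One sweep: exactly ``L**2`` random single-site update attempts.

    The lattice is updated in place (and also returned).  Downhill
    acceptance consumes a uniform draw that is simply ignored, keeping the
    number of random draws per sweep fixed.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    L = spins.shape[0]
    n = L * L
    si = rng.integers(0, L, size=n)
    sj = rng.integers(0, L, size=n)
    u = rng.random(n)
    _attempts(spins, float(T), float(H), si, sj, u)
    return spins


def magnetization(spins: np.ndarray) -> float:
    """Mean spin over the lattice, in [-1, 1]."""
    return float(spins.mean())


def perturb_alignment(
    spins: np.ndarray,
    r: float,
    rng: np.random.Generator,
    equilibrium_sign: int,
) -> np.ndarray:
    """Reset every spin independently: equilibrium sign with probability ``r``.

    With probability ``1 - r`` a spin is set to the opposite sign, so
    ``r = 1`` reproduces the aligned equilibrium state, ``r = 0.5`` an
    unordered state and ``r = 0`` the fully flipped state.  Returns a new
    lattice; the input is not modified.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("alignment probability r must lie in [0, 1]")
    if equilibrium_sign not in (-1, 1):
        raise ValueError("equilibrium_sign must be -1 or +1")
    keep = rng.random(spins.shape) < r
    out = np.where(keep, equilibrium_sign, -equilibrium_sign).astype(np.int8)
    return out


def simulate_lattice(cfg: LatticeConfig, track_site: tuple[int, int] | None = None):
    """Run a lattice simulation following the configured schedules.

    Returns a :class:`Trajectory` of the magnetization recorded every
    ``record_every`` sweeps (including the initial state).  If
    ``track_site`` is given, the trajectory's ``meta["site_trace"]``
    carries that site's spin at the same recording times.
    """
    rng = np.random.default_rng(cfg.seed)
    spins = random_lattice(cfg.L, rng, cfg.init)
    temps = cfg._schedule(cfg.temperature)
    fields = cfg._schedule(cfg.field_schedule)

    n_records = cfg.sweeps // cfg.record_every
    values = np.empty(n_records + 1)
    params = np.empty(n_records + 1)
    site = np.empty(n_records + 1, dtype=np.int8) if track_site else None

    swept = "T" if np.ndim(cfg.temperature) else "H"
    sched = temps if swept == "T" else fields
    values[0] = magnetization(spins)
    params[0] = sched[0]
    if track_site:
        site[0] = spins[track_site]

    rec = 1
    L2 = cfg.L * cfg.L
    for sweep in range(cfg.sweeps):
        si = rng.integers(0, cfg.L, size=L2)
        sj = rng.integers(0, cfg.L, size=L2)
        u = rng.random(L2)
        _attempts(spins, temps[sweep], fields[sweep], si, sj, u)
        if (sweep + 1) % cfg.record_every == 0:
            values[rec] = magnetization(spins)
            params[rec] = sched[sweep]
            if track_site:
                site[rec] = spins[track_site]
            rec += 1

    traj = Trajectory(
        values[:rec],
        dt=float(cfg.record_every),
        parameter_name=swept,
        parameter_values=params[:rec],
        seed=cfg.seed,
    )
    traj.meta["final_spins"] = spins
    if track_site:
        traj.meta["site_trace"] = site[:rec]
        traj.meta["site"] = track_site
    return traj


def hysteresis_loop(cfg: LatticeConfig) -> tuple[Trajectory, Trajectory]:
    """Up-then-down field loop at fixed temperature.

    ``cfg.field_schedule`` must be the up-leg ramp (array); the down leg
    retraces it in reverse, continuing from the up leg's final lattice.
    Returns the two magnetization-vs-H traces.
    """
    fields = np.asarray(cfg.field_schedule, dtype=float)
    if fields.ndim != 1 or len(fields) != cfg.sweeps:
        raise ValueError("hysteresis_loop needs a per-sweep field ramp")
    up = simulate_lattice(cfg)
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    spins = up.meta["final_spins"].copy()
    temps = cfg._schedule(cfg.temperature)
    down_fields = fields[::-1]
    n_records = cfg.sweeps // cfg.record_every
    values = np.empty(n_records + 1)
    params = np.empty(n_records + 1)
    values[0] = magnetization(spins)
    params[0] = down_fields[0]
    rec = 1
    L2 = cfg.L * cfg.L
    for sweep in range(cfg.sweeps):
        si = rng.integers(0, cfg.L, size=L2)
        sj = rng.integers(0, cfg.L, size=L2)
        u = rng.random(L2)
        _attempts(spins, temps[sweep], down_fields[sweep], si, sj, u)
        if (sweep + 1) % cfg.record_every == 0:
            values[rec] = magnetization(spins)
            params[rec] = down_fields[sweep]
            rec += 1
    down = Trajectory(values[:rec], dt=float(cfg.record_every), parameter_name="H",
                      parameter_values=params[:rec], seed=cfg.seed)
    down.meta["final_spins"] = spins
    return up, down


def transition_field(traj: Trajectory) -> float:
    """Field at which the magnetization first crosses zero (NaN if never)."""
    values = traj.values
    params = traj.parameter_array()
    sign0 = np.sign(values[0]) or 1.0
    crossed = np.nonzero(np.sign(values) == -sign0)[0]
    if len(crossed) == 0:
        return float("nan")
    return float(params[crossed[0]])


@dataclass
class SiteProbabilityTrace:
    """Empirical per-time probability of one site being in a given state."""

    site: tuple[int, int]
    state: int
    probability: np.ndarray


def site_state_probability(
    site_traces: np.ndarray,
    state: int,
    site: tuple[int, int] = (0, 0),
) -> SiteProbabilityTrace:
    """Fraction of realizations in which a site holds ``state`` per record.

    ``site_traces`` is an (R, n_records) array of that site's spins across
    an ensemble of R >= 2 runs (see ``simulate_lattice(..., track_site=...)``).
    """
    traces = np.asarray(site_traces)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need an (R, n_records) array with R >= 2 realizations")
    if state not in (-1, 1):
        raise ValueError("state must be -1 or +1")
    prob = (traces == state).mean(axis=0)
    return SiteProbabilityTrace(site=site, state=state, probability=prob)
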