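"""Univariate state trajectories with their parameter context.

Both model backends (the mean-field difference equation and the 2D lattice)
report their observable -- the magnetization -- as a :class:`Trajectory`,
so the perturbation-recovery machinery and the indicator suite can stay
model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A magnetization time series together with the driving parameter.

    Parameters
    ----------
    values
        State values ``M_t``; length ``n_steps + 1`` including the initial
        state.  Lattice magnetizations lie in ``[-1, 1]``; mean-field states
        may transiently exceed that range after a perturbation.
    dt
        Time-step size the series was generated with (1.0 for lattice sweeps).
    parameter_name
        Which parameter provided the context, ``"H"`` or ``"T"``.
    parameter_values
        Scalar (fixed parameter) or per-step array (ramp); when an array it
        has the same length as ``values``.
    seed
        Seed used to generate the series, if any.
    """

    values: np.ndarray
    dt: float = 0.1
    parameter_name: str = "H"
    parameter_values: float | np.ndarray = 0.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.ndim(self.parameter_values) > 0:
            self.parameter_values = np.asarray(self.parameter_values, dtype=float)
            if len(self.parameter_values) != len(self.values):
                raise ValueError(
                    "per-step parameter schedule must match the trajectory length"
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def parameter_array(self) -> np.ndarray:
        """Parameter value per recorded state, broadcast if constant."""
        if np.ndim(self.parameter_values) == 0:
            return np.full(len(self.values), float(self.parameter_values))
        return self.parameter_values
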