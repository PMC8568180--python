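"""Critical-slowing-down bifurcation estimator.

Given ensemble-averaged recovery curves at increasing values of the
critical parameter, the estimator

1. takes first-order discrete differences of each mean recovery curve,
2. restricts them to the pre-equilibrium segment (the part of the curve
   before the state first re-enters a band around its equilibrium),
3. approximates that segment with a least-squares polynomial and takes
   the maximum of the fitted curve,
4. regresses the per-curve maxima linearly against the parameter values
   and extrapolates the line to the zero-line.

The zero crossing is the parameter at which no recovery would take place
any more -- the estimated bifurcation point.  A variant collects fitted
difference values at matched relative positions along each segment and
extrapolates each of those to zero, tracing an approximation of the
equilibrium curve near the bifurcation.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError
from .recovery import RecoveryCurve

__all__ = [
    "FittedSlope",
    "BifurcationEstimate",
    "EquilibriumCurveEstimate",
    "difference_curve",
    "recovery_segment",
    "fit_slope",
    "analyze_curve",
    "estimate_bifurcation",
    "estimate_equilibrium_curve",
]

_DENSE_GRID = 1000  # evaluation points for the fitted-polynomial maximum


def _curve_values(recovery) -> np.ndarray:
    if isinstance(recovery, RecoveryCurve):
        return recovery.mean
    return np.asarray(recovery, dtype=float)


def difference_curve(recovery) -> np.ndarray:
    """First-order discrete differences ``d(t) = y(t+1) - y(t)``."""
    y = _curve_values(recovery)
    if len(y) < 2:
        raise EstimationError("recovery curve too short to difference")
    return np.diff(y)


def recovery_segment(recovery: RecoveryCurve, epsilon_frac: float = 0.05) -> range:
    """Indices of the not-yet-recovered part of the curve.

    Runs from 0 up to (exclusive) the first index at which the state is
    within ``epsilon_frac`` of its initial displacement from the
    equilibrium reference; the whole curve if the band is never reached.
    """
    y = recovery.mean
    band = epsilon_frac * abs(y[0] - recovery.y_eq)
    inside = np.abs(y - recovery.y_eq) <= band
    hits = np.nonzero(inside)[0]
    stop = int(hits[0]) if len(hits) else len(y)
    return range(0, stop)


@dataclass
class FittedSlope:
    """Polynomial fit of one difference curve over its recovery segment."""

    c: float
    differences: np.ndarray
    segment: range
    polynomial: np.polynomial.Polynomial
    degree: int
    t_star: float  # argmax of the fitted polynomial (index units)
    m_max: float  # maximum fitted difference value
    state_at_max: float | None = None  # y(t*) on the mean recovery curve
    segment_states: np.ndarray | None = None


def fit_slope(
    differences: np.ndarray,
    segment: range,
    degree: int = 4,
    states: np.ndarray | None = None,
    c: float = np.nan,
) -> FittedSlope:
    """Least-squares polynomial fit of the differences over ``segment``.

    The reported maximum is taken over the fitted polynomial evaluated on
    a dense grid (1000 points) across the segment, not over the raw
    differences.  ``states`` (the mean recovery curve) optionally supplies
    the state value at the maximum.
    """
    if not 2 <= degree <= 8:
        raise ValueError("polynomial degree must be between 2 and 8")
    differences = np.asarray(differences, dtype=float)
    idx = np.asarray(segment)
    idx = idx[idx < len(differences)]
    if len(idx) <= degree:
        raise EstimationError(
            f"insufficient recovery segment ({len(idx)} points for degree {degree})"
        )
    poly = np.polynomial.Polynomial.fit(idx, differences[idx], degree)
    grid = np.linspace(idx[0], idx[-1], _DENSE_GRID)
    fitted = poly(grid)
    k = int(np.argmax(fitted))
    t_star = float(grid[k])
    state_at_max = None
    seg_states = None
    if states is not None:
        states = np.asarray(states, dtype=float)
        state_at_max = float(np.interp(t_star, np.arange(len(states)), states))
        seg_states = states[idx]
    return FittedSlope(
        c=float(c), differences=differences, segment=range(int(idx[0]), int(idx[-1]) + 1),
        polynomial=poly, degree=degree, t_star=t_star, m_max=float(fitted[k]),
        state_at_max=state_at_max, segment_states=seg_states,
    )


def analyze_curve(
    recovery: RecoveryCurve, degree: int = 4, epsilon_frac: float = 0.05
) -> FittedSlope:
    """Difference, segment and fit of one recovery curve in a single call."""
    d = difference_curve(recovery)
    seg = recovery_segment(recovery, epsilon_frac)
    return fit_slope(d, seg, degree=degree, states=recovery.mean, c=recovery.c)


@dataclass
class BifurcationEstimate:
    """Linear extrapolation of fitted maxima to the zero-line."""

    pairs: list[tuple[float, float]]  # (c_i, m_i)
    slope: float
    intercept: float
    c_hat: float
    r_squared: float
    warnings: list[str] = field(default_factory=list)


def estimate_bifurcation(pairs) -> BifurcationEstimate:
    """Ordinary least-squares line through ``(c_i, m_i)``; zero crossing.

    With exactly two pairs the line passes through both points.  A zero
    slope is degenerate and raises :class:`EstimationError`; a zero
    crossing between the perturbation parameters while all maxima share
    one sign is allowed but flagged with a warning.
    """
    pairs = [(float(c), float(m)) for c, m in pairs]
    cs = np.array([p[0] for p in pairs])
    ms = np.array([p[1] for p in pairs])
    if len(np.unique(cs)) < 2:
        raise EstimationError("need at least two distinct parameter values")
    slope, intercept = np.polyfit(cs, ms, 1)
    # a slope that moves the maxima by less than numerical noise across the
    # whole parameter range is degenerate (e.g. identical maxima everywhere)
    m_scale = max(1e-300, float(np.abs(ms).max()))
    if abs(slope) * (cs.max() - cs.min()) < 1e-10 * max(1.0, m_scale):
        raise EstimationError("zero slope: fitted maxima do not change with c")
    c_hat = -intercept / slope
    ss_res = float(np.sum((ms - (slope * cs + intercept)) ** 2))
    ss_tot = float(np.sum((ms - ms.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot

    warn: list[str] = []
    if cs.min() < c_hat < cs.max() and (np.all(ms < 0) or np.all(ms > 0)):
        warn.append("zero crossing lies between the perturbation parameters")
    est = BifurcationEstimate(
        pairs=pairs, slope=float(slope), intercept=float(intercept),
        c_hat=float(c_hat), r_squared=r_squared, warnings=warn,
    )
    for w in warn:
        _warnings.warn(w, stacklevel=2)
    return est


@dataclass
class EquilibriumCurveEstimate:
    """Estimated (parameter, state) points tracing the equilibrium curve."""

    points: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.points)


def estimate_equilibrium_curve(
    slopes: list[FittedSlope],
    q_levels: np.ndarray | None = None,
) -> EquilibriumCurveEstimate:
    """Equilibrium-curve approximation from matched relative positions.

    For each relative position ``q`` along the fitted segments, the fitted
    difference values across curves are regressed against the parameter and
    extrapolated to zero, giving one parameter value; pairing it with the
    mean state at ``q`` yields one curve point.  Levels at which the
    regression is degenerate (zero slope) are skipped; fewer than two
    usable levels raise :class:`EstimationError`.
    """
    if len(slopes) < 2:
        raise EstimationError("need at least two fitted slopes")
    if q_levels is None:
        q_levels = np.round(np.arange(0.1, 0.91, 0.1), 10)
    points: list[tuple[float, float]] = []
    for q in q_levels:
        ds, cs, ys = [], [], []
        for s in slopes:
            t_q = s.segment.start + q * (len(s.segment) - 1)
            ds.append(float(s.polynomial(t_q)))
            cs.append(s.c)
            if s.segment_states is not None:
                pos = q * (len(s.segment_states) - 1)
                ys.append(float(np.interp(pos, np.arange(len(s.segment_states)),
                                          s.segment_states)))
        slope, intercept = np.polyfit(cs, ds, 1)
        if abs(slope) < 1e-15:
            continue
        c_star = -intercept / slope
        state = float(np.mean(ys)) if ys else float("nan")
        points.append((float(c_star), state))
    if len(points) < 2:
        raise EstimationError("fewer than two usable q-levels (zero slope)")
    return EquilibriumCurveEstimate(points=points)
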