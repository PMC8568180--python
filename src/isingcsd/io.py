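"""Delimited-text readers and writers for all pipeline artifacts.

Trajectories travel as CSV with columns ``time, state, parameter`` plus a
JSON sidecar echoing the generating configuration; recovery curves as CSV
with columns ``c, step, mean, sd``; estimates as JSON; indicator traces
and equilibrium curves as CSV.  Everything round-trips through pandas.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import BifurcationEstimate, EquilibriumCurveEstimate
from .ews import EWSTrace
from .recovery import RecoveryCurve
from .trajectory import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "read_series",
    "write_recovery_curves",
    "read_recovery_curves",
    "write_estimate",
    "write_equilibrium_curve",
    "write_ews_trace",
    "config_to_json",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, range):
        return [obj.start, obj.stop]
    return obj


def config_to_json(config, path: str | Path) -> None:
    """Echo any configuration dataclass (or dict) as a JSON sidecar."""
    Path(path).write_text(json.dumps(_jsonable(config), indent=2) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path,
                     config=None) -> None:
    """CSV with columns time, state, parameter (+ optional JSON sidecar)."""
    path = Path(path)
    df = pd.DataFrame(
        {"time": traj.time, "state": traj.values, "parameter": traj.parameter_array()}
    )
    df.to_csv(path, index=False)
    if config is not None:
        config_to_json(config, path.with_suffix(".json"))


def read_trajectory(path: str | Path, dt: float | None = None,
                    parameter_name: str = "H") -> Trajectory:
    df = pd.read_csv(path)
    values = df["state"].to_numpy()
    if dt is None:
        times = df["time"].to_numpy()
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    params = df["parameter"].to_numpy() if "parameter" in df else 0.0
    return Trajectory(values, dt=dt, parameter_name=parameter_name,
                      parameter_values=params)


def read_series(path: str | Path, column: str | int | None = None) -> np.ndarray:
    """A univariate series from comma-delimited text.

    Accepts the package's trajectory CSV (uses the ``state`` column), a
    named column, a column index, or a headerless (single or multi)
    column file.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"no data in {path}") from exc
    if isinstance(column, str):
        return df[column].to_numpy(dtype=float)
    if "state" in df.columns and column is None:
        return df["state"].to_numpy(dtype=float)
    try:  # a numeric "header" means the file has no header row
        float(str(df.columns[0]))
    except ValueError:
        pass
    else:
        df = pd.read_csv(path, header=None)
    return df.iloc[:, column if isinstance(column, int) else 0].to_numpy(dtype=float)


def write_recovery_curves(curves: list[RecoveryCurve], path: str | Path,
                          spec=None) -> None:
    """Long-format CSV: columns c, step, mean, sd."""
    path = Path(path)
    frames = [
        pd.DataFrame({
            "c": curve.c,
            "step": np.arange(len(curve.mean)),
            "mean": curve.mean,
            "sd": curve.sd,
        })
        for curve in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if spec is not None:
        config_to_json(spec, path.with_suffix(".json"))


def read_recovery_curves(path: str | Path) -> list[RecoveryCurve]:
    df = pd.read_csv(path)
    curves = []
    for c, group in df.groupby("c", sort=True):
        group = group.sort_values("step")
        mean = group["mean"].to_numpy()
        curves.append(RecoveryCurve(
            c=float(c), mean=mean, sd=group["sd"].to_numpy(),
            y_eq=float(mean[-1]), n_realizations=0,
        ))
    return curves


def write_estimate(estimate: BifurcationEstimate, path: str | Path,
                   slopes=None, extra: dict | None = None) -> None:
    """Estimate JSON: inputs, regression line, c_hat, diagnostics."""
    payload = {
        "pairs": [{"c": c, "m": m} for c, m in estimate.pairs],
        "slope": estimate.slope,
        "intercept": estimate.intercept,
        "c_hat": estimate.c_hat,
        "r_squared": estimate.r_squared,
        "warnings": estimate.warnings,
    }
    if slopes is not None:
        payload["maxima"] = [
            {"c": s.c, "t_star": s.t_star, "m_max": s.m_max,
             "state_at_max": s.state_at_max}
            for s in slopes
        ]
    if extra:
        payload.update(_jsonable(extra))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_equilibrium_curve(curve: EquilibriumCurveEstimate,
                            path: str | Path) -> None:
    pd.DataFrame(curve.points, columns=["parameter", "state"]).to_csv(
        path, index=False
    )


def write_ews_trace(trace: EWSTrace, path: str | Path) -> None:
    """One row per window, one column per indicator."""
    df = pd.DataFrame({"window_end": trace.window_end, **trace.values})
    df.to_csv(path, index=False)
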