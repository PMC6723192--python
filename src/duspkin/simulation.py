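"""Time-course integration and d5 inhibition scans.

The Herceptin*HER2 mass-action term creates rates of order 1e4 next to
relaxation rates of order 1, so the system is moderately stiff; the default
integrator is LSODA with tight tolerances.  A scan varies only the DUSP
inactivation rate d5 — the model's inhibition knob — over a grid and labels
each trajectory's survival regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    KineticParameters,
    NumericsError,
    STATE_NAMES,
    Topology,
    ValidationError,
    initial_state,
    rhs,
)

__all__ = ["SolverOptions", "Trajectory", "ScanEntry", "ScanResult",
           "simulate", "inhibition_scan"]


@dataclass(frozen=True)
class SolverOptions:
    """Integration horizon, output grid and tolerances.

    t_end = 10 model-time units lets the slowest mode (DUSP relaxation at rate
    k5 + d5 >= 1, MAPK pairs faster) equilibrate so the asymptotic survival
    slope dominates the trajectory tail.
    """

    t_end: float = 10.0
    n_points: int = 1001
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    method: str = "LSODA"  # stiff-capable adaptive integrator

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValidationError(f"t_end must be > 0, got {self.t_end}")
        if self.n_points < 2:
            raise ValidationError(f"n_points must be >= 2, got {self.n_points}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValidationError("tolerances must be > 0")

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_points)


@dataclass(frozen=True)
class Trajectory:
    """One integrated run: time grid, state matrix and full provenance."""

    time: np.ndarray  # (n_points,), strictly increasing from 0
    states: np.ndarray  # (n_points, 11) in STATE_NAMES order
    params: KineticParameters
    topology: Topology
    options: SolverOptions

    def __getitem__(self, name: str) -> np.ndarray:
        """Column access by state name, e.g. traj["Survival"]."""
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def survival(self) -> np.ndarray:
        return self["Survival"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.time)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class ScanEntry:
    """One grid point of an inhibition scan.

    ``error`` is set (and trajectory/metrics are None) when integration failed
    for this d5; failures never abort the rest of the scan.
    """

    d5: float
    trajectory: Trajectory | None
    regime: str | None
    metrics: "object | None"  # SurvivalMetrics; typed loosely to avoid a cycle
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass(frozen=True)
class ScanResult:
    entries: tuple[ScanEntry, ...]
    params: KineticParameters
    topology: Topology
    options: SolverOptions
    eps_frac: float = 0.01
    delta_frac: float = 0.05

    def entry(self, d5: float) -> ScanEntry:
        for e in self.entries:
            if e.d5 == d5:
                return e
        raise KeyError(f"no scan entry at d5={d5}")

    def summary(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row: dict = {"d5": e.d5, "regime": e.regime, "error": e.error}
            if e.metrics is not None:
                row.update(
                    s0=e.metrics.s0, s_end=e.metrics.s_end,
                    s_max=e.metrics.s_max, t_at_max=e.metrics.t_at_max,
                    range=e.metrics.range,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "topology": self.topology.name,
            "eps_frac": self.eps_frac,
            "delta_frac": self.delta_frac,
            "entries": self.summary().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def simulate(
    params: KineticParameters,
    topology: Topology | str = Topology.CONSTITUTIVE,
    options: SolverOptions | None = None,
) -> Trajectory:
    """Integrate the model from the standard initial state.

    Deterministic for fixed inputs; raises NumericsError with the solver
    message if the integrator fails.
    """
    topology = Topology.coerce(topology)
    options = options or SolverOptions()
    y0 = initial_state(params).to_array()
    t_eval = options.time_grid
    sol = solve_ivp(
        rhs,
        (0.0, options.t_end),
        y0,
        t_eval=t_eval,
        args=(params, topology),
        method=options.method,
        rtol=options.rel_tol,
        atol=options.abs_tol,
    )
    if not sol.success:
        raise NumericsError(f"integration failed: {sol.message}")
    return Trajectory(
        time=t_eval, states=sol.y.T.copy(), params=params,
        topology=topology, options=options,
    )


def inhibition_scan(
    params: KineticParameters,
    topology: Topology | str,
    d5_values: "list[float] | np.ndarray",
    options: SolverOptions | None = None,
    eps_frac: float = 0.01,
    delta_frac: float = 0.05,
) -> ScanResult:
    """Simulate once per d5 in ``d5_values`` (all other parameters fixed) and
    label each survival trajectory's regime.

    Individual integration failures are recorded per entry rather than
    aborting the scan.
    """
    from .trajectories import classify_regime, survival_metrics

    topology = Topology.coerce(topology)
    options = options or SolverOptions()
    d5_values = [float(v) for v in d5_values]
    if not d5_values:
        raise ValidationError("d5_values must be nonempty")
    if any(v < 0 for v in d5_values):
        raise ValidationError("d5 values must be >= 0")
    if sorted(d5_values) != d5_values or len(set(d5_values)) != len(d5_values):
        raise ValidationError("d5 values must be strictly increasing")

    entries = []
    for d5 in d5_values:
        p = replace(params, d5=d5)
        try:
            traj = simulate(p, topology, options)
            metrics = survival_metrics(traj)
            regime = classify_regime(metrics, eps_frac, delta_frac)
            entries.append(ScanEntry(d5, traj, regime.name, metrics))
        except NumericsError as exc:
            entries.append(ScanEntry(d5, None, None, None, error=str(exc)))
    return ScanResult(
        entries=tuple(entries), params=params, topology=topology,
        options=options, eps_frac=eps_frac, delta_frac=delta_frac,
    )
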