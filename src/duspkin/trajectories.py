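"""Survival-trajectory metrics, regime classification, conservation checks.

Classification mirrors the three qualitative survival behaviours seen when
DUSP inhibition strength (d5) is raised: monotone growth (INCREASING), a
substantial rise followed by a fall (INFLECTED), and near-immediate decline
(DECREASING).  The decision is shape-only: it depends on the survival curve
only through ratios of its excursions, so it is invariant to affine rescaling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PROTEINS, ValidationError
from .simulation import ScanResult, Trajectory

__all__ = [
    "SurvivalMetrics",
    "RegimeLabel",
    "survival_metrics",
    "classify_regime",
    "eventually_decreases",
    "eventual_decrease_threshold",
    "conservation_check",
]


@dataclass(frozen=True)
class SurvivalMetrics:
    """Scalar summaries of one survival curve, computed on the output grid
    (no interpolation): initial/final/maximum value, time of maximum, and
    range = max - min."""

    s0: float
    s_end: float
    s_max: float
    t_at_max: float
    range: float


class RegimeLabel(enum.Enum):
    INCREASING = "INCREASING"
    INFLECTED = "INFLECTED"
    DECREASING = "DECREASING"


def survival_metrics(traj: Trajectory) -> SurvivalMetrics:
    s = np.asarray(traj.survival, dtype=float)
    t = np.asarray(traj.time, dtype=float)
    if s.size == 0:
        raise ValidationError("empty trajectory")
    i_max = int(np.argmax(s))
    return SurvivalMetrics(
        s0=float(s[0]),
        s_end=float(s[-1]),
        s_max=float(s[i_max]),
        t_at_max=float(t[i_max]),
        range=float(s.max() - s.min()),
    )


def classify_regime(
    metrics: SurvivalMetrics,
    eps_frac: float = 0.01,
    delta_frac: float = 0.05,
) -> RegimeLabel:
    """Label a survival curve from its metrics.

    INCREASING when the maximum is effectively terminal
    (s_max - s_end <= eps_frac * range); otherwise INFLECTED when the interior
    rise is substantial (s_max - s0 > delta_frac * range), else DECREASING.
    A flat curve (zero range) is INCREASING by convention.
    """
    if not (0 < eps_frac < 1 and 0 < delta_frac < 1):
        raise ValidationError("eps_frac and delta_frac must lie in (0, 1)")
    if metrics.range == 0.0:
        return RegimeLabel.INCREASING
    if metrics.s_max - metrics.s_end <= eps_frac * metrics.range:
        return RegimeLabel.INCREASING
    if metrics.s_max - metrics.s0 > delta_frac * metrics.range:
        return RegimeLabel.INFLECTED
    return RegimeLabel.DECREASING


def eventually_decreases(metrics: SurvivalMetrics, eps_frac: float = 0.01) -> bool:
    """True when the final survival value sits below the running maximum by
    more than eps_frac of the range, i.e. the curve is INFLECTED or
    DECREASING."""
    if metrics.range == 0.0:
        return False
    return metrics.s_max - metrics.s_end > eps_frac * metrics.range


def eventual_decrease_threshold(
    scan: ScanResult, eps_frac: float = 0.01
) -> float | None:
    """Smallest scanned d5 whose survival trajectory eventually decreases;
    None when no scanned strength reverses growth (the Herceptin-resistant
    phenotype persists at every tested inhibition level)."""
    if not scan.entries:
        raise ValidationError("empty scan")
    for e in scan.entries:
        if e.ok and eventually_decreases(e.metrics, eps_frac):
            return e.d5
    return None


def conservation_check(traj: Trajectory, tol: float = 1e-6) -> pd.DataFrame:
    """Per-protein maximum deviation of active+inactive from the configured
    total, relative when the total is positive and absolute otherwise;
    ``exceeds_tol`` flags violations."""
    rows = []
    for p in PROTEINS:
        total = traj.params.totals[p]
        pair_sum = traj[f"{p}ac"] + traj[f"{p}i"]
        dev = np.abs(pair_sum - total)
        if total > 0:
            dev = dev / total
        max_dev = float(dev.max())
        rows.append({
            "protein": p,
            "total": total,
            "max_deviation": max_dev,
            "relative": total > 0,
            "exceeds_tol": max_dev > tol,
        })
    return pd.DataFrame(rows)
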