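"""Survival metrics, regime classification and conservation reporting."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duspkin import (
    RegimeLabel,
    SolverOptions,
    Topology,
    ValidationError,
    build_parameters,
    classify_regime,
    conservation_check,
    eventual_decrease_threshold,
    eventual_survival_slope,
    eventually_decreases,
    inhibition_scan,
    simulate,
    survival_metrics,
)
from duspkin.simulation import Trajectory
from duspkin.trajectories import SurvivalMetrics
from conftest import D5_GRID


def toy_trajectory(survival, ref_params):
    """Trajectory with a prescribed survival column (other states constant at
    the conserved split), for shape-only classification tests."""
    survival = np.asarray(survival, dtype=float)
    n = survival.size
    states = np.zeros((n, 11))
    for i in range(0, 10, 2):
        states[:, i] = 40.0
        states[:, i + 1] = 60.0
    states[:, 10] = survival
    return Trajectory(
        time=np.linspace(0, 1, n), states=states, params=ref_params,
        topology=Topology.CONSTITUTIVE, options=SolverOptions(t_end=1.0,
                                                              n_points=n),
    )


class TestSurvivalMetrics:
    def test_monotone_ramp(self, ref_params):
        m = survival_metrics(toy_trajectory([0, 1, 2, 3], ref_params))
        assert m.s_max == 3.0
        assert m.t_at_max == 1.0
        assert m.s_end == 3.0 and m.s0 == 0.0 and m.range == 3.0

    def test_interior_peak(self, ref_params):
        m = survival_metrics(toy_trajectory([0, 5, 2], ref_params))
        assert m.s_max == 5.0 and m.s_end == 2.0
        assert m.t_at_max == 0.5

    def test_constant_curve_zero_range(self, ref_params):
        m = survival_metrics(toy_trajectory([2.0, 2.0, 2.0], ref_params))
        assert m.range == 0.0


class TestClassifyRegime:
    def test_ramp_is_increasing(self, ref_params):
        m = survival_metrics(toy_trajectory(np.arange(11.0), ref_params))
        assert classify_regime(m) is RegimeLabel.INCREASING

    def test_flat_curve_increasing_by_convention(self, ref_params):
        m = survival_metrics(toy_trajectory([1.0, 1.0], ref_params))
        assert classify_regime(m) is RegimeLabel.INCREASING

    def test_rise_then_fall_is_inflected(self, ref_params):
        m = survival_metrics(toy_trajectory([0, 8, 10, 6, 2], ref_params))
        assert classify_regime(m) is RegimeLabel.INFLECTED

    def test_brief_transient_then_fall_is_decreasing(self, ref_params):
        m = survival_metrics(
            toy_trajectory([0, 0.2, -3, -6, -10], ref_params))
        assert classify_regime(m) is RegimeLabel.DECREASING

    def test_reference_run_d5_20_increasing(self, fast_opts):
        traj = simulate(build_parameters({"d5": 20}), options=fast_opts)
        assert classify_regime(survival_metrics(traj)) is RegimeLabel.INCREASING

    def test_reference_run_d5_50_inflected(self, fast_opts):
        traj = simulate(build_parameters({"d5": 50}), options=fast_opts)
        assert classify_regime(survival_metrics(traj)) is RegimeLabel.INFLECTED

    def test_threshold_fractions_validated(self, ref_params):
        m = survival_metrics(toy_trajectory([0, 1.0], ref_params))
        with pytest.raises(ValidationError):
            classify_regime(m, eps_frac=0.0)
        with pytest.raises(ValidationError):
            classify_regime(m, delta_frac=1.5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        survival=st.lists(
            st.floats(-100, 100, allow_nan=False, allow_infinity=False),
            min_size=3, max_size=30),
        scale=st.floats(0.01, 50.0),
        shift=st.floats(-1000, 1000),
    )
    def test_affine_invariance(self, survival, scale, shift):
        """The label depends only on the curve's shape: positive affine
        rescaling of the survival values never changes it."""
        base = SurvivalMetrics(
            s0=survival[0], s_end=survival[-1], s_max=max(survival),
            t_at_max=0.0, range=max(survival) - min(survival),
        )
        scaled_vals = [scale * s + shift for s in survival]
        scaled = SurvivalMetrics(
            s0=scaled_vals[0], s_end=scaled_vals[-1],
            s_max=max(scaled_vals), t_at_max=0.0,
            range=max(scaled_vals) - min(scaled_vals),
        )
        assert classify_regime(base) is classify_regime(scaled)


class TestEventualDecreaseThreshold:
    def test_constitutive_threshold_is_50(self, ref_params, fast_opts):
        scan = inhibition_scan(ref_params, Topology.CONSTITUTIVE, D5_GRID,
                               fast_opts)
        assert eventual_decrease_threshold(scan) == 50.0

    @pytest.mark.parametrize("topology", [Topology.ERK12, Topology.JNK12])
    def test_induced_topologies_never_decrease(self, topology, ref_params,
                                               fast_opts):
        scan = inhibition_scan(ref_params, topology, D5_GRID, fast_opts)
        assert eventual_decrease_threshold(scan) is None

    def test_single_zero_entry_has_no_threshold(self, ref_params, fast_opts):
        scan = inhibition_scan(ref_params, Topology.CONSTITUTIVE, [0.0],
                               fast_opts)
        assert eventual_decrease_threshold(scan) is None

    @pytest.mark.parametrize("topology", list(Topology))
    def test_threshold_matches_slope_sign_change(self, topology, ref_params,
                                                 fast_opts):
        """The trajectory-based threshold coincides with the first scanned d5
        whose closed-form asymptotic survival slope is negative."""
        scan = inhibition_scan(ref_params, topology, D5_GRID, fast_opts)
        slopes = {
            d5: eventual_survival_slope(build_parameters({"d5": d5}), topology)
            for d5 in D5_GRID
        }
        analytic = next((d5 for d5 in D5_GRID if slopes[d5] < 0), None)
        assert eventual_decrease_threshold(scan) == analytic


class TestConservationCheck:
    def test_valid_trajectory_within_tolerance(self, ref_params, fast_opts):
        traj = simulate(ref_params, options=fast_opts)
        report = conservation_check(traj, tol=1e-6)
        assert not report["exceeds_tol"].any()
        assert report["max_deviation"].max() <= 1e-6

    def test_injected_violation_flagged(self, ref_params, fast_opts):
        traj = simulate(ref_params, options=fast_opts)
        states = traj.states.copy()
        states[:, 1] += 1.0  # perturb HER2i
        bad = replace(traj, states=states)
        report = conservation_check(bad, tol=1e-6).set_index("protein")
        assert bool(report.loc["HER2", "exceeds_tol"])
        assert not bool(report.loc["ERK12", "exceeds_tol"])

    def test_zero_total_reported_absolute(self, fast_opts):
        p = build_parameters({"total_JNK12": 0.0})
        traj = simulate(p, options=fast_opts)
        report = conservation_check(traj).set_index("protein")
        assert not bool(report.loc["JNK12", "relative"])
        assert report.loc["JNK12", "max_deviation"] <= 1e-8


def test_eventually_decreases_consistent_with_labels(ref_params, fast_opts):
    scan = inhibition_scan(ref_params, Topology.CONSTITUTIVE, D5_GRID,
                           fast_opts)
    for e in scan.entries:
        expected = e.regime in ("INFLECTED", "DECREASING")
        assert eventually_decreases(e.metrics) == expected
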