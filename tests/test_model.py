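"""Unit and property tests for the kinetic model core: parameter building,
initial state, derivatives, conservation structure and closed-form steady
states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duspkin import (
    ConfigurationError,
    KineticParameters,
    ModelState,
    PROTEINS,
    STATE_NAMES,
    Topology,
    ValidationError,
    build_parameters,
    derivatives,
    eventual_survival_slope,
    initial_state,
    steady_state,
)
from duspkin.model import rhs


class TestBuildParameters:
    def test_reference_defaults(self):
        p = build_parameters({})
        assert p.herceptin == 100.0
        assert p.hill == 0.6
        assert all(getattr(p, n) == 1.0 for n in
                   ("k1", "k2", "k3", "k4", "k5", "d1", "d2", "d3", "d4",
                    "d5", "s1", "s2"))
        assert p.totals == {prot: 100.0 for prot in PROTEINS}

    def test_single_override_leaves_rest(self):
        p = build_parameters({"d5": 500})
        assert p.d5 == 500.0
        assert p.k5 == 1.0 and p.herceptin == 100.0

    def test_total_override(self):
        p = build_parameters({"total_HER2": 250})
        assert p.totals["HER2"] == 250.0
        assert p.totals["ERK12"] == 100.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            build_parameters({"k3": -1})

    def test_nonpositive_hill_rejected(self):
        with pytest.raises(ValidationError):
            build_parameters({"hill": 0.0})

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError, match="k99"):
            build_parameters({"k99": 1.0})


class TestInitialState:
    def test_prescribed_actives(self, ref_params):
        s = initial_state(ref_params)
        assert s.HER2ac == 100.0 and s.ERK12ac == 100.0 and s.DUSPac == 100.0
        assert s.JNK12ac == 0.0 and s.P38ac == 0.0
        assert s.Survival == 0.0

    def test_inactive_pools_complement_totals(self, ref_params):
        s = initial_state(ref_params)
        assert s.HER2i == 0.0 and s.ERK12i == 0.0 and s.DUSPi == 0.0
        assert s.JNK12i == 100.0 and s.P38i == 100.0

    def test_infeasible_total_rejected(self):
        with pytest.raises(ValidationError, match="HER2"):
            initial_state(build_parameters({"total_HER2": 50}))


class TestDerivatives:
    def test_hand_values_at_initial_state(self, ref_params):
        d = derivatives(initial_state(ref_params), ref_params)
        # survival: s1*100 - s2*(0*0)**0.6
        assert d.Survival == pytest.approx(100.0)
        # HER2: k1*0 - d1*100*100
        assert d.HER2ac == pytest.approx(-10000.0)
        assert d.HER2i == pytest.approx(10000.0)

    def test_all_zero_amounts_give_zero_protein_rates(self, ref_params):
        zero = ModelState(**{n: 0.0 for n in STATE_NAMES})
        d = derivatives(zero, ref_params)
        assert all(getattr(d, n) == 0.0 for n in STATE_NAMES[:-1])

    def test_negative_amount_rejected(self, ref_params):
        s = initial_state(ref_params)
        bad = ModelState(**{**{n: getattr(s, n) for n in STATE_NAMES},
                            "JNK12ac": -1.0})
        with pytest.raises(ValidationError, match="JNK12ac"):
            derivatives(bad, ref_params)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        amounts=st.lists(st.floats(0, 1e3, allow_nan=False), min_size=10,
                         max_size=10),
        rates=st.lists(st.floats(0, 10, allow_nan=False), min_size=12,
                       max_size=12),
        topology=st.sampled_from(list(Topology)),
    )
    def test_pair_fluxes_cancel_exactly(self, amounts, rates, topology):
        """d(ac)/dt + d(i)/dt == 0 identically for every protein pair,
        regardless of state, parameters or topology."""
        names = ("k1", "k2", "k3", "k4", "k5", "d1", "d2", "d3", "d4", "d5",
                 "s1", "s2")
        params = build_parameters(dict(zip(names, rates)))
        y = np.array(amounts + [0.0])
        dy = rhs(0.0, y, params, topology)
        for i in range(0, 10, 2):
            assert dy[i] + dy[i + 1] == 0.0


class TestSteadyState:
    def test_constitutive_dusp_closed_form(self):
        ss = steady_state(build_parameters({"d5": 1}), Topology.CONSTITUTIVE)
        assert ss.DUSPac == pytest.approx(50.0)

    def test_slope_sign_flips_across_grid(self):
        # weak inhibition sustains growth, strong inhibition reverses it
        assert eventual_survival_slope(build_parameters({"d5": 20})) > 0
        s50 = eventual_survival_slope(build_parameters({"d5": 50}))
        assert s50 < 0
        assert s50 == pytest.approx(49.7512 - 67.744, abs=0.05)

    def test_erk12_topology_slope_positive_at_strong_inhibition(self):
        s = eventual_survival_slope(build_parameters({"d5": 500}),
                                    Topology.ERK12)
        assert s > 0
        assert s == pytest.approx(49.7512 - 15.586, abs=0.05)

    def test_jnk12_topology_quadratic_root(self):
        """The JNK12-induced DUSP fixed point solves a quadratic; cross-check
        the closed form against a damped fixed-point iteration."""
        params = build_parameters({"d5": 500})
        ss = steady_state(params, Topology.JNK12)

        her2 = params.k1 * 100 / (params.k1 + params.d1 * params.herceptin)
        a = params.k3 * her2
        x = 1.0
        for _ in range(20000):
            jnk = a * 100 / (a + params.d3 * x)
            target = params.k5 * jnk * 100 / (params.k5 * jnk + params.d5)
            x = 0.99 * x + 0.01 * target
        assert ss.DUSPac == pytest.approx(x, rel=1e-6)
        assert ss.DUSPac == pytest.approx(3.8954, abs=1e-3)

    def test_zero_survival_weights_give_zero_slope(self):
        p = build_parameters({"s1": 0, "s2": 0})
        assert eventual_survival_slope(p) == 0.0

    @pytest.mark.parametrize("topology", list(Topology))
    def test_active_values_within_totals(self, topology):
        for d5 in (0.5, 5.0, 50.0, 500.0):
            ss = steady_state(build_parameters({"d5": d5}), topology)
            for name in ("HER2ac", "ERK12ac", "JNK12ac", "P38ac", "DUSPac"):
                assert 0.0 <= getattr(ss, name) <= 100.0

    @pytest.mark.parametrize("topology", list(Topology))
    def test_dusp_steady_strictly_decreasing_in_d5(self, topology):
        grid = [0.1, 1, 5, 20, 50, 100, 500, 2000]
        vals = [steady_state(build_parameters({"d5": d}), topology).DUSPac
                for d in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("topology", list(Topology))
    def test_fixed_point_zeroes_the_derivatives(self, topology):
        """Substituting the closed-form steady state into the ODE right-hand
        side must give protein rates at round-off level."""
        params = build_parameters({"d5": 50})
        ss = steady_state(params, topology)
        y = np.array([
            ss.HER2ac, 100 - ss.HER2ac,
            ss.ERK12ac, 100 - ss.ERK12ac,
            ss.JNK12ac, 100 - ss.JNK12ac,
            ss.P38ac, 100 - ss.P38ac,
            ss.DUSPac, 100 - ss.DUSPac,
            0.0,
        ])
        dy = rhs(0.0, y, params, topology)
        assert np.max(np.abs(dy[:-1])) <= 1e-8

    def test_slope_matches_survival_rate_at_fixed_point(self):
        params = build_parameters({"d5": 100})
        ss = steady_state(params, Topology.CONSTITUTIVE)
        expected = params.s1 * ss.ERK12ac - params.s2 * (
            ss.JNK12ac * ss.P38ac) ** params.hill
        assert ss.eventual_survival_slope == pytest.approx(expected)


def test_state_array_round_trip(ref_params):
    s = initial_state(ref_params)
    assert ModelState.from_array(s.to_array()) == s


def test_kinetic_parameters_reject_bad_totals():
    with pytest.raises(ValidationError):
        KineticParameters(totals={"HER2": 100.0})
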