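"""Topology wiring and the lumped RLC dynamics against analytic oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import perfusim as ps
from perfusim.network import (
    Branch,
    CirculationTopology,
    NodeSpec,
    build_topology,
    compartment_derivatives,
)
from perfusim.parameters import ConfigurationError


class TestBuildTopology:
    def test_head_branch_fed_from_arch_drained_into_svc(self, params):
        topo = build_topology(params)
        names = {(b.src, b.dst) for b in topo.branches}
        assert ("AA1", "HD") in names
        assert ("HD", "SVC") in names

    def test_two_leg_compartments_with_full_rc_chain(self, params):
        topo = build_topology(params)
        for leg, ven in (("LLE", "lleg_ven"), ("RLE", "rleg_ven")):
            node = next(n for n in topo.nodes if n.name == leg)
            assert node.C > 0
            assert any(b.src == "ABII" and b.dst == leg for b in topo.branches)
            assert any(b.name == ven and b.dst == "AbdVC" for b in topo.branches)

    def test_missing_head_compliance_names_symbol(self, params):
        broken = params.model_copy(deep=True)
        broken.compartments["HD"].C = 0.0
        with pytest.raises(ConfigurationError, match="C_HD"):
            build_topology(broken)

    def test_missing_compartment_is_reported(self, params):
        broken = params.model_copy(deep=True)
        del broken.compartments["KID"]
        with pytest.raises(ConfigurationError, match="KID"):
            build_topology(broken)

    def test_every_tap_references_existing_vertex(self, params):
        topo = build_topology(params)
        vertices = set(topo.node_names) | set(topo.boundaries)
        assert set(topo.taps.values()) <= vertices

    def test_dangling_compartment_rejected(self):
        with pytest.raises(ConfigurationError, match="dangling"):
            CirculationTopology(
                nodes=[NodeSpec("A", 1.0, 0.0, 0.0), NodeSpec("B", 1.0, 0.0, 0.0)],
                branches=[Branch("ab", "A", "A2", 1.0)],
                boundaries=["A2"],
            )

    def test_unknown_branch_vertex_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown vertex"):
            CirculationTopology(
                nodes=[NodeSpec("A", 1.0, 0.0, 0.0)],
                branches=[Branch("ab", "A", "NOWHERE", 1.0)],
                boundaries=[],
            )


def _rc_topology(R=0.5, C=2.0):
    return CirculationTopology(
        nodes=[NodeSpec("tank", C, 0.0, 0.0)],
        branches=[Branch("drain", "tank", "sink", R)],
        boundaries=["sink"],
    )


class TestCompartmentDerivatives:
    def test_ohmic_discharge_rate(self):
        """Single RC compartment with no inflow: dV/dt = -P0/R."""
        topo = _rc_topology(R=0.5, C=2.0)
        P0 = 10.0
        dstate = compartment_derivatives(np.array([2.0 * P0]), topo, {"sink": 0.0})
        assert dstate[0] == pytest.approx(-P0 / 0.5)

    def test_equilibrium_has_zero_derivatives(self):
        """Two equal-pressure compartments exchange no net flow."""
        topo = CirculationTopology(
            nodes=[NodeSpec("a", 1.0, 0.0, 0.0), NodeSpec("b", 2.0, 0.0, 0.0)],
            branches=[Branch("f", "a", "b", 1.0), Branch("r", "b", "a", 1.0)],
            boundaries=[],
        )
        dstate = compartment_derivatives(np.array([5.0, 10.0]), topo)
        assert np.allclose(dstate, 0.0, atol=1e-14)

    def test_non_finite_state_names_variable(self):
        topo = _rc_topology()
        with pytest.raises(FloatingPointError, match="tank"):
            compartment_derivatives(np.array([np.nan]), topo, {"sink": 0.0})

    def test_rc_discharge_matches_exponential(self):
        """P(t) = P0 exp(-t/RC) to better than 1e-6 relative."""
        R, C, P0 = 0.8, 1.5, 20.0
        topo = _rc_topology(R=R, C=C)
        sol = solve_ivp(
            lambda t, y: compartment_derivatives(y, topo, {"sink": 0.0}),
            (0.0, 3.0 * R * C), [C * P0], rtol=1e-12, atol=1e-12, dense_output=True)
        ts = np.linspace(0.0, 3.0 * R * C, 40)
        p_num = sol.sol(ts)[0] / C
        p_ref = P0 * np.exp(-ts / (R * C))
        assert np.max(np.abs(p_num - p_ref)) / P0 < 1e-6

    def test_rlc_step_matches_damped_oscillator(self):
        """Step response of a series RLC charging a compliance.

        Closed form for the underdamped node pressure:
        P(t) = Ps [1 - e^(-a t)(cos wd t + a/wd sin wd t)].
        """
        R, L, C, Ps = 0.05, 5e-3, 1.0, 50.0
        topo = CirculationTopology(
            nodes=[NodeSpec("node", C, 0.0, 0.0)],
            branches=[Branch("feed", "src", "node", R, L, "inertial")],
            boundaries=["src"],
        )
        a = R / (2.0 * L)
        wd = math.sqrt(1.0 / (L * C) - a * a)
        t_end = 6.0 / a
        sol = solve_ivp(
            lambda t, y: compartment_derivatives(y, topo, {"src": Ps}),
            (0.0, t_end), [0.0, 0.0], rtol=1e-12, atol=1e-12, dense_output=True)
        ts = np.linspace(0.0, t_end, 200)
        p_num = sol.sol(ts)[0] / C
        p_ref = Ps * (1.0 - np.exp(-a * ts) * (np.cos(wd * ts) + a / wd * np.sin(wd * ts)))
        assert np.max(np.abs(p_num - p_ref)) / Ps < 1e-6

    def test_solutions_converge_as_inertance_vanishes(self):
        """Max pressure deviation from the L = 0 solution falls monotonically."""
        R, C, Ps = 0.5, 1.0, 30.0
        t_end = 5.0 * R * C
        ts = np.linspace(0.0, t_end, 100)
        p_alg = Ps * (1.0 - np.exp(-ts / (R * C)))  # algebraic (L = 0) charging curve
        errs = []
        for L in (1e-3, 1e-4, 1e-5):
            topo = CirculationTopology(
                nodes=[NodeSpec("node", C, 0.0, 0.0)],
                branches=[Branch("feed", "src", "node", R, L, "inertial")],
                boundaries=["src"],
            )
            sol = solve_ivp(
                lambda t, y: compartment_derivatives(y, topo, {"src": Ps}),
                (0.0, t_end), [0.0, 0.0], rtol=1e-10, atol=1e-10, dense_output=True)
            errs.append(np.max(np.abs(sol.sol(ts)[0] / C - p_alg)))
        assert errs[0] > errs[1] > errs[2]
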