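"""Unit and property tests for the membrane/synapse/gating primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpgnet.core import (GatingParams, NeuronParams, NeuronState, SynapseParams,
                         gating_derivative, gating_steady_state,
                         gating_time_constant, membrane_derivative,
                         synaptic_conductance)


class TestGatingSteadyState:
    def test_midpoint_is_half(self):
        gate = GatingParams(A=1.0, S=0.5, E_half=-40.0, tau=10.0)
        assert gating_steady_state(-40.0, gate) == pytest.approx(0.5)

    def test_sigmoid_limits(self):
        gate = GatingParams(A=1.0, S=0.5, E_half=-40.0, tau=10.0)
        assert gating_steady_state(1e4, gate) == pytest.approx(0.0, abs=1e-12)
        assert gating_steady_state(-1e4, gate) == pytest.approx(1.0, abs=1e-12)

    def test_against_direct_formula(self):
        # A = 0.5, S = -0.046/mV, V = E_half - 20 mV, evaluated independently
        gate = GatingParams(A=0.5, S=-0.046, E_half=-35.0, tau=5.0)
        expected = 1.0 / (1.0 + 0.5 * np.exp(-0.046 * (-20.0)))
        assert gating_steady_state(-55.0, gate) == pytest.approx(expected, rel=1e-12)
        assert gating_steady_state(-55.0, gate) == pytest.approx(0.4435, abs=5e-4)

    @given(V=st.floats(-200, 200), A=st.floats(0.01, 10.0),
           S=st.floats(-1.0, 1.0), E=st.floats(-80, 0))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, V, A, S, E):
        gate = GatingParams(A=A, S=S, E_half=E, tau=1.0)
        z = gating_steady_state(V, gate)
        assert 0.0 <= z <= 1.0
        if abs(S * (V - E)) < 30:  # away from float saturation
            assert 0.0 < z < 1.0
        z2 = gating_steady_state(V + 1.0, gate)
        if S > 1e-6:
            assert z2 <= z
        elif S < -1e-6:
            assert z2 >= z

    def test_zero_A_pins_at_one(self):
        gate = GatingParams(A=0.0, S=0.0, E_half=0.0, tau=1.0)
        assert gating_steady_state(-120.0, gate) == 1.0


class TestGatingKinetics:
    def test_fixed_point(self):
        assert gating_derivative(0.3, 0.3, 7.0) == 0.0

    def test_rate_arithmetic(self):
        assert gating_derivative(0.0, 1.0, 2.0) == pytest.approx(0.5)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            gating_derivative(0.1, 0.5, 0.0)
        with pytest.raises(ValueError):
            GatingParams(A=1.0, S=0.1, E_half=0.0, tau=-1.0)

    def test_relaxation_matches_exponential(self):
        # forward-integrate one gate at fixed V; the trajectory must follow
        # z(t) = z_inf + (z0 - z_inf) exp(-t / tau)
        gate = GatingParams(A=0.5, S=0.3, E_half=-50.0, tau=40.0)
        V, z0, dt = -45.0, 0.1, 0.01
        z_inf = gating_steady_state(V, gate)
        z = z0
        for k in range(4000):
            z = z + dt * gating_derivative(z, z_inf, gate.tau)
        t = 4000 * dt
        expected = z_inf + (z0 - z_inf) * np.exp(-t / gate.tau)
        assert z == pytest.approx(expected, abs=1e-4)

    def test_voltage_dependent_tau_is_bell_shaped(self):
        gate = GatingParams(A=0.5, S=0.3, E_half=-51.0, tau=300.0,
                            tau_voltage_dependent=True)
        v = np.linspace(-90, -10, 401)
        tau = gating_time_constant(v, gate)
        peak = v[np.argmax(tau)]
        # peak sits where z_inf = 1/2, i.e. A exp(S (V - E)) = 1
        v_half = gate.E_half + np.log(1.0 / gate.A) / gate.S
        assert peak == pytest.approx(v_half, abs=0.5)
        assert tau[0] < tau.max() and tau[-1] < tau.max()
        # constant-tau gates report tau everywhere
        const = GatingParams(A=0.5, S=0.3, E_half=-51.0, tau=300.0)
        assert np.all(gating_time_constant(v, const) == 300.0)

    def test_voltage_dependent_tau_requires_A(self):
        with pytest.raises(ValueError):
            GatingParams(A=0.0, S=0.3, E_half=-51.0, tau=10.0,
                         tau_voltage_dependent=True)


class TestSynapticConductance:
    SYN = SynapseParams(g_max=2.0, E_syn=-40.0, E_lo=-60.0, E_hi=-40.0)

    @pytest.mark.parametrize("v_pre, expected", [
        (-70.0, 0.0),          # below lower threshold
        (-50.0, 1.0),          # midpoint of ramp -> g_max/2
        (-35.0, 2.0),          # saturation above E_hi
        (-60.0, 0.0),          # exactly at E_lo
        (-40.0, 2.0),          # exactly at E_hi
    ])
    def test_piecewise_values(self, v_pre, expected):
        assert synaptic_conductance(v_pre, self.SYN) == pytest.approx(expected)

    @given(v=st.floats(-100, 0))
    @settings(max_examples=200, deadline=None)
    def test_bounded_monotone_continuous(self, v):
        g = synaptic_conductance(v, self.SYN)
        assert 0.0 <= g <= self.SYN.g_max
        assert synaptic_conductance(v + 0.5, self.SYN) >= g
        # Lipschitz on the ramp: slope never exceeds g_max / (E_hi - E_lo)
        slope = (synaptic_conductance(v + 1e-3, self.SYN) - g) / 1e-3
        assert slope <= self.SYN.g_max / (self.SYN.E_hi - self.SYN.E_lo) + 1e-6

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(g_max=1.0, E_syn=-40.0, E_lo=-50.0, E_hi=-50.0)


class TestMembraneDerivative:
    def test_rest_equilibrium(self):
        p = NeuronParams(C=5.0, G_leak=1.0, E_rest=-60.0)
        assert membrane_derivative(NeuronState(V=-60.0), p) == 0.0

    def test_single_term_arithmetic(self):
        p = NeuronParams(C=1.0, G_leak=1.0, E_rest=-60.0)
        assert membrane_derivative(NeuronState(V=-50.0), p) == pytest.approx(-10.0)

    def test_full_rhs_term_by_term(self):
        # one active synapse plus active persistent sodium, checked against
        # an independent term-by-term evaluation
        m_gate = GatingParams(A=1.0, S=-0.2, E_half=-45.0, tau=2.0)
        h_gate = GatingParams(A=0.5, S=0.3, E_half=-51.0, tau=190.0)
        p = NeuronParams(C=5.0, G_leak=1.0, E_rest=-60.0, G_Na=1.85, E_Na=50.0,
                         m_gate=m_gate, h_gate=h_gate)
        state = NeuronState(V=-50.0, m=0.3, h=0.6)
        syn = [(0.8, -40.0)]
        got = membrane_derivative(state, p, syn, I_app=1.5)
        expected = (1.0 * (-60.0 + 50.0)
                    + 0.8 * (-40.0 + 50.0)
                    + 1.85 * (50.0 + 50.0) * 0.3 * 0.6
                    + 1.5) / 5.0
        assert got == pytest.approx(expected, rel=1e-12)

    @given(I=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_applied_current(self, I):
        p = NeuronParams(C=5.0, G_leak=1.0, E_rest=-60.0)
        s = NeuronState(V=-55.0)
        base = membrane_derivative(s, p, I_app=0.0)
        assert membrane_derivative(s, p, I_app=I) == pytest.approx(base + I / p.C)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(C=0.0, G_leak=1.0, E_rest=-60.0)
        with pytest.raises(ValueError):
            NeuronParams(C=1.0, G_leak=-1.0, E_rest=-60.0)
        with pytest.raises(ValueError):
            NeuronState(V=-60.0, m=1.5)
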