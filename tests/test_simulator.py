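"""Integrator correctness: closed forms, determinism, invariances."""

import numpy as np
import pytest

import cpgnet as c
from cpgnet.core import NeuronParams
from cpgnet.network import NetworkSpec, NeuronSpec
from cpgnet.simulate import CompiledNetwork, initial_state


def passive_cell(name="cell", C=5.0, G=1.0):
    p = NeuronParams(C=C, G_leak=G, E_rest=-60.0)
    return NetworkSpec(neurons=[NeuronSpec(name, "MN", p)])


@pytest.fixture(scope="module")
def chain():
    return c.build_two_layer_chain()


class TestInitialState:
    def test_rest_and_gate_steady_state(self, chain):
        comp = CompiledNetwork(chain)
        V, m, h = initial_state(comp)
        assert np.allclose(V, comp.E_rest)
        assert np.allclose(m, comp.z_inf(V, comp.mA, comp.mS, comp.mE))
        assert np.allclose(h, comp.z_inf(V, comp.hA, comp.hS, comp.hE))

    def test_symmetric_half_center_stays_symmetric_unkicked(self):
        rg = c.build_rhythm_generator()
        tr = c.run(rg, config=c.SimulationConfig(duration=1.0))
        assert np.allclose(tr["L_limb_RG_EXT"], tr["L_limb_RG_FLX"], atol=1e-9)


class TestStartupKick:
    def test_documented_protocol(self, chain):
        kick = c.startup_kick(chain)
        assert kick.target == "L_limb_RG_EXT"
        assert (kick.amplitude, kick.t_on, kick.t_off) == (2.0, 0.0, 0.5)

    def test_kick_breaks_symmetry(self):
        rg = c.build_rhythm_generator()
        tr = c.run(rg, [c.startup_kick(rg)], config=c.SimulationConfig(duration=2.0))
        assert not np.allclose(tr["L_limb_RG_EXT"][-5000:],
                               tr["L_limb_RG_FLX"][-5000:], atol=1.0)

    def test_zero_amplitude_is_identity(self, chain):
        null = c.StimulusProtocol("L_limb_RG_EXT", 0.0, 0.0, 0.5)
        a = c.run(chain, [null], config=c.SimulationConfig(duration=0.5))
        b = c.run(chain, config=c.SimulationConfig(duration=0.5))
        assert np.array_equal(a.V, b.V)


class TestClosedForms:
    def test_passive_step_response(self):
        # V(t) = E_rest + (I/G)(1 - exp(-t G / C))
        net = passive_cell()
        tr = c.run(net, [c.StimulusProtocol("cell", 2.0, 0.0, 1.0)],
                   config=c.SimulationConfig(dt=0.1, duration=1.0))
        t_ms = tr.time * 1000.0
        expected = -60.0 + 2.0 * (1.0 - np.exp(-t_ms / 5.0))
        assert np.abs(tr["cell"] - expected).max() < 1e-3

    def test_relaxation_time_constant(self):
        # convergence to E_rest + I/G with time constant C/G
        net = passive_cell(C=10.0, G=2.0)
        tr = c.run(net, [c.StimulusProtocol("cell", 4.0, 0.0, 2.0)],
                   config=c.SimulationConfig(dt=0.05, duration=2.0))
        v = tr["cell"]
        assert v[-1] == pytest.approx(-58.0, abs=1e-6)
        # at t = tau = C/G = 5 ms the response reaches 63.2% of the step
        i_tau = int(5.0 / 0.05)
        assert v[i_tau] == pytest.approx(-60.0 + 2.0 * (1 - np.exp(-1)), abs=1e-3)


class TestDeterminismAndInvariance:
    def test_bitwise_determinism_with_noise(self, chain):
        noise = c.NoiseSpec(targets=("L_limb_RG_EXT",), sd=0.5, seed=11)
        cfg = c.SimulationConfig(duration=1.0)
        a = c.run(chain, [c.startup_kick(chain)], noise, cfg)
        b = c.run(chain, [c.startup_kick(chain)], noise, cfg)
        assert np.array_equal(a.V, b.V)
        assert a.provenance["noise"]["seed"] == 11

    def test_different_seed_differs(self, chain):
        cfg = c.SimulationConfig(duration=1.0)
        a = c.run(chain, [c.startup_kick(chain)],
                  c.NoiseSpec(("L_limb_RG_EXT",), 0.5, 1), cfg)
        b = c.run(chain, [c.startup_kick(chain)],
                  c.NoiseSpec(("L_limb_RG_EXT",), 0.5, 2), cfg)
        assert not np.array_equal(a.V, b.V)

    def test_time_shift_invariance(self):
        # the dynamics are autonomous: starting from an equilibrium, shifting
        # every stimulus by delta shifts the whole response by delta.  A
        # passive motoneuron layer rests at a true fixed point, unlike the
        # oscillator circuits whose rest state immediately drifts.
        mn = c.build_motoneuron_layer("hip")
        delta = 0.4
        stim = c.StimulusProtocol("L_hip_MN_EXT", 6.0, 0.5, 1.5)
        shifted = c.StimulusProtocol("L_hip_MN_EXT", 6.0, 0.5 + delta, 1.5 + delta)
        a = c.run(mn, [stim], config=c.SimulationConfig(duration=2.0))
        b = c.run(mn, [shifted], config=c.SimulationConfig(duration=2.0 + delta))
        ba = c.burst_bounds(a.time, a["L_hip_MN_EXT"], -55.0)
        bb = c.burst_bounds(b.time, b["L_hip_MN_EXT"], -55.0)
        assert np.allclose(bb.onsets - delta, ba.onsets, atol=1e-4)
        assert np.allclose(bb.offsets - delta, ba.offsets, atol=1e-4)

    def test_gates_stay_in_unit_interval(self, chain):
        tr = c.run(chain, [c.startup_kick(chain)],
                   config=c.SimulationConfig(duration=2.0, record_gates=True))
        assert tr.m.min() >= 0.0 and tr.m.max() <= 1.0
        assert tr.h.min() >= 0.0 and tr.h.max() <= 1.0


class TestNumericalQuality:
    def test_dt_refinement_converges(self):
        # near the converged regime, halving dt moves every sample < 0.1 mV
        limb = c.build_limb()
        kick = c.startup_kick(limb)
        a = c.run(limb, [kick], config=c.SimulationConfig(dt=0.005, duration=1.0,
                                                          record_gates=False))
        b = c.run(limb, [kick], config=c.SimulationConfig(dt=0.0025, duration=1.0,
                                                          record_gates=False))
        assert np.abs(a.V - b.V[::2]).max() < 0.1

    def test_integrators_agree(self):
        rg = c.build_rhythm_generator()
        kick = c.startup_kick(rg)
        a = c.run(rg, [kick], config=c.SimulationConfig(dt=0.01, duration=0.5,
                                                        record_gates=False))
        b = c.run(rg, [kick], config=c.SimulationConfig(dt=0.01, duration=0.5,
                                                        integrator="rk4",
                                                        record_gates=False))
        assert np.abs(a.V - b.V).max() < 0.5

    def test_rk4_fourth_order_on_smooth_problem(self):
        # passive cell under constant current: rk4 global error ~ dt^4
        net = passive_cell()
        stim = [c.StimulusProtocol("cell", 2.0, 0.0, 0.05)]

        def err(dt):
            tr = c.run(net, stim, config=c.SimulationConfig(
                dt=dt, duration=0.05, integrator="rk4"))
            t_ms = tr.time * 1000.0
            exact = -60.0 + 2.0 * (1.0 - np.exp(-t_ms / 5.0))
            return np.abs(tr["cell"] - exact).max()

        e1, e2 = err(0.8), err(0.4)
        assert e1 / e2 > 12  # ~16 for clean 4th order

    def test_unknown_stimulus_target_rejected(self, chain):
        with pytest.raises(c.SimulationError, match="ghost"):
            c.run(chain, [c.StimulusProtocol("ghost", 1.0, 0.0, 0.1)],
                  config=c.SimulationConfig(duration=0.2))

    def test_divergence_aborts_with_location(self):
        # exponential Euler is unconditionally stable, but explicit RK4 on a
        # badly stiff cell overflows; the abort must name the neuron
        p = NeuronParams(C=1e-8, G_leak=10.0, E_rest=-60.0)
        net = NetworkSpec(neurons=[NeuronSpec("frail", "MN", p)])
        with pytest.raises(c.SimulationError, match="frail"):
            c.run(net, [c.StimulusProtocol("frail", 1e3, 0.0, 1.0)],
                  config=c.SimulationConfig(dt=0.1, duration=1.0, integrator="rk4"))
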