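"""Topology builders, validation, serialization round-trips."""

import numpy as np
import pytest

import cpgnet as c
from cpgnet.network import Diagnostic, NetworkError, compose
from cpgnet.core import NeuronParams, SynapseParams


@pytest.fixture(scope="module")
def table():
    return c.default_parameter_table()


class TestRhythmGenerator:
    def test_four_neurons(self, table):
        rg = c.build_rhythm_generator(table=table)
        assert len(rg.neurons) == 4
        assert sorted(n.role for n in rg.neurons) == ["IN", "IN", "RG", "RG"]

    def test_mutual_excitation_and_crossed_inhibition(self, table):
        rg = c.build_rhythm_generator(table=table)
        by = {(s.pre, s.post): s for s in rg.synapses}
        direct = by[("L_limb_RG_EXT", "L_limb_RG_FLX")]
        assert direct.sign == "excitatory"
        relay = by[("L_limb_RG_EXT", "L_limb_IN_EXT")]
        inhib = by[("L_limb_IN_EXT", "L_limb_RG_FLX")]
        assert relay.sign == "excitatory" and inhib.sign == "inhibitory"

    def test_oscillator_neurons_carry_persistent_sodium(self, table):
        rg = c.build_rhythm_generator(table=table)
        for n in rg.neurons:
            if n.role == "RG":
                assert n.params.G_Na > 0
            else:
                assert n.params.G_Na == 0

    def test_missing_parameter_class_is_an_error(self, table):
        import copy
        broken = copy.deepcopy(table)
        del broken.neurons["RG"]
        with pytest.raises(Exception, match="RG"):
            c.build_rhythm_generator(table=broken)


class TestPatternFormationAndMotoneurons:
    def test_kneeankle_is_one_shared_group(self, table):
        pf = c.build_pattern_formation("kneeankle", table=table)
        assert {n.joint for n in pf.neurons} == {"kneeankle"}
        assert len(pf.find(role="PF")) == 2

    def test_pf_mutual_inhibition_paths(self, table):
        pf = c.build_pattern_formation("hip", table=table)
        pairs = {(s.pre, s.post) for s in pf.synapses}
        assert ("L_hip_PF_EXT", "L_hip_IN_EXT") in pairs
        assert ("L_hip_IN_EXT", "L_hip_PF_FLX") in pairs
        assert ("L_hip_IN_FLX", "L_hip_PF_EXT") in pairs

    def test_unknown_joint_rejected(self, table):
        with pytest.raises(NetworkError):
            c.build_pattern_formation("elbow", table=table)

    def test_each_mn_has_renshaw_loop(self, table):
        mn = c.build_motoneuron_layer("knee", table=table)
        pairs = {(s.pre, s.post): s.sign for s in mn.synapses}
        assert pairs[("L_knee_MN_EXT", "L_knee_RE_EXT")] == "excitatory"
        assert pairs[("L_knee_RE_EXT", "L_knee_MN_EXT")] == "inhibitory"

    def test_mn_rests_without_drive(self, table):
        mn = c.build_motoneuron_layer("knee", table=table)
        tr = c.run(mn, config=c.SimulationConfig(duration=0.3))
        assert abs(tr["L_knee_MN_EXT"][-1] + 60.0) < 1e-9


class TestLimb:
    def test_six_motoneurons(self, table):
        limb = c.build_limb(table=table)
        assert len(limb.find(role="MN")) == 6

    def test_knee_and_ankle_share_pf_source(self, table):
        limb = c.build_limb(table=table)
        pre_of = {s.post: s.pre for s in limb.synapses if s.post.endswith("MN_EXT")}
        assert pre_of["L_knee_MN_EXT"] == pre_of["L_ankle_MN_EXT"] == "L_kneeankle_PF_EXT"

    def test_two_limbs_share_nothing(self, table):
        left = c.build_limb("left", table=table)
        right = c.build_limb("right", table=table)
        both = compose(left, right)
        left_names = set(left.neuron_names())
        for s in both.synapses:
            assert (s.pre in left_names) == (s.post in left_names)

    def test_builders_deterministic(self, table):
        import yaml
        a = yaml.safe_dump(c.build_limb(table=table).to_dict(), sort_keys=True)
        b = yaml.safe_dump(c.build_limb(table=table).to_dict(), sort_keys=True)
        assert a == b

    def test_duplicate_composition_rejected(self, table):
        limb = c.build_limb(table=table)
        with pytest.raises(NetworkError):
            compose(limb, limb)


class TestBaselineCircuit:
    def test_half_center_direct_to_motoneurons(self, table):
        net = c.build_single_joint_baseline(table=table)
        assert not net.find(role="PF")
        pairs = {(s.pre, s.post) for s in net.synapses}
        assert ("L_hip_RG_EXT", "L_hip_MN_EXT") in pairs


class TestValidation:
    def test_all_builders_validate_clean(self, table):
        for net in (c.build_rhythm_generator(table=table),
                    c.build_two_layer_chain(table=table),
                    c.build_limb(table=table),
                    c.build_single_joint_baseline(table=table)):
            errors = [d for d in c.validate_network(net) if d.severity == "error"]
            assert errors == []

    def test_dangling_synapse_reported(self, table):
        net = c.build_rhythm_generator(table=table)
        bad = c.SynapseSpec(pre="L_limb_RG_EXT", post="ghost",
                            params=SynapseParams(1.0, -40.0, -50.0, -35.0),
                            sign="excitatory")
        net.synapses.append(bad)
        diags = c.validate_network(net)
        assert any("ghost" in d.message for d in diags)

    def test_sodium_on_interneuron_warns(self, table):
        net = c.build_rhythm_generator(table=table)
        hot = c.NeuronSpec("L_limb_IN_BAD", "IN",
                           table.neuron("RG"), "left", "limb", "none")
        net.neurons.append(hot)
        diags = c.validate_network(net)
        assert any(d.severity == "warning" and "IN_BAD" in d.message for d in diags)

    def test_sign_inconsistency_reported(self, table):
        net = c.build_rhythm_generator(table=table)
        wrong = c.SynapseSpec.__new__(c.SynapseSpec)
        object.__setattr__(wrong, "pre", "L_limb_RG_EXT")
        object.__setattr__(wrong, "post", "L_limb_RG_FLX")
        object.__setattr__(wrong, "params", SynapseParams(1.0, -100.0, -50.0, -35.0))
        object.__setattr__(wrong, "sign", "excitatory")
        net.synapses.append(wrong)
        diags = c.validate_network(net)
        assert any("labeled excitatory" in d.message for d in diags)


class TestSerialization:
    def test_yaml_round_trip_lossless(self, tmp_path, table):
        net = c.build_limb(table=table)
        p = tmp_path / "limb.yaml"
        net.save(p)
        again = c.NetworkSpec.load(p)
        assert again.to_dict() == net.to_dict()
        # second round trip byte-identical
        p2 = tmp_path / "limb2.yaml"
        again.save(p2)
        assert p.read_text() == p2.read_text()

    def test_json_round_trip(self, tmp_path, table):
        net = c.build_two_layer_chain(table=table)
        p = tmp_path / "chain.json"
        net.save(p)
        assert c.NetworkSpec.load(p).to_dict() == net.to_dict()
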