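"""Builders for the named locomotor network topologies.

The circuit hierarchy is three-layered: a four-neuron half-center *rhythm
generator* (RG; two persistent-sodium neurons mutually excited by weak direct
synapses and mutually inhibited via interneurons) sets step-cycle timing; per
joint-group *pattern formation* (PF) half-centers reshape that timing; and a
motoneuron layer (MN with Renshaw-cell recurrent inhibition) produces the
output.  The knee and ankle share one PF group (a fixed muscle synergy), so a
limb has two PF groups driving six motoneurons.

Neurons are named ``SIDE_JOINT_ROLE_POLARITY`` (e.g. ``L_hip_PF_EXT``) for
unambiguous stimulus targeting.  Builders are deterministic and never mutate
their inputs; every built topology passes :func:`validate_network` cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Literal

import yaml

from .core import NeuronParams, SynapseParams
from .params import ParameterTable

__all__ = [
    "NeuronSpec", "SynapseSpec", "NetworkSpec", "NetworkError",
    "build_rhythm_generator", "build_pattern_formation", "build_motoneuron_layer",
    "build_limb", "build_single_joint_baseline", "build_two_layer_chain",
    "compose", "validate_network",
]

Role = Literal["RG", "PF", "MN", "IN", "RE"]
Side = Literal["left", "right", "none"]
Joint = Literal["hip", "knee", "ankle", "kneeankle", "limb", "none"]

_SIDE_PREFIX = {"left": "L", "right": "R", "none": "X"}


class NetworkError(ValueError):
    """Structural problem while building or composing a network."""


@dataclass(frozen=True)
class NeuronSpec:
    name: str
    role: Role
    params: NeuronParams
    side: Side = "none"
    joint: Joint = "none"
    polarity: Literal["extensor", "flexor", "none"] = "none"


@dataclass(frozen=True)
class SynapseSpec:
    pre: str
    post: str
    params: SynapseParams
    sign: Literal["excitatory", "inhibitory"]

    def __post_init__(self) -> None:
        if self.pre == self.post:
            raise NetworkError(f"self-synapse on {self.pre!r} not allowed")


@dataclass
class NetworkSpec:
    """A named collection of neurons and directed graded synapses."""

    neurons: list[NeuronSpec] = field(default_factory=list)
    synapses: list[SynapseSpec] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def neuron_names(self) -> list[str]:
        return [n.name for n in self.neurons]

    def neuron(self, name: str) -> NeuronSpec:
        for n in self.neurons:
            if n.name == name:
                return n
        raise KeyError(f"no neuron named {name!r} in network")

    def find(self, role: str | None = None, side: str | None = None,
             joint: str | None = None, polarity: str | None = None) -> list[str]:
        """Names of neurons matching all given attribute filters."""
        out = []
        for n in self.neurons:
            if role is not None and n.role != role:
                continue
            if side is not None and n.side != side:
                continue
            if joint is not None and n.joint != joint:
                continue
            if polarity is not None and n.polarity != polarity:
                continue
            out.append(n.name)
        return out

    # ------------------------------------------------------------------ i/o
    def to_dict(self) -> dict[str, Any]:
        return {
            "metadata": dict(self.metadata),
            "neurons": [
                {
                    "name": n.name, "role": n.role, "side": n.side,
                    "joint": n.joint, "polarity": n.polarity,
                    "params": {
                        "C": n.params.C, "G_leak": n.params.G_leak,
                        "E_rest": n.params.E_rest, "G_Na": n.params.G_Na,
                        "E_Na": n.params.E_Na,
                        "m": {"A": n.params.m_gate.A, "S": n.params.m_gate.S,
                              "E_half": n.params.m_gate.E_half, "tau": n.params.m_gate.tau,
                              "tau_voltage_dependent": n.params.m_gate.tau_voltage_dependent},
                        "h": {"A": n.params.h_gate.A, "S": n.params.h_gate.S,
                              "E_half": n.params.h_gate.E_half, "tau": n.params.h_gate.tau,
                              "tau_voltage_dependent": n.params.h_gate.tau_voltage_dependent},
                    },
                }
                for n in self.neurons
            ],
            "synapses": [
                {
                    "pre": s.pre, "post": s.post, "sign": s.sign,
                    "params": {"g_max": s.params.g_max, "E_syn": s.params.E_syn,
                               "E_lo": s.params.E_lo, "E_hi": s.params.E_hi},
                }
                for s in self.synapses
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "NetworkSpec":
        from .core import GatingParams

        neurons = []
        for n in raw.get("neurons", []):
            p = n["params"]
            neurons.append(NeuronSpec(
                name=n["name"], role=n["role"], side=n.get("side", "none"),
                joint=n.get("joint", "none"), polarity=n.get("polarity", "none"),
                params=NeuronParams(
                    C=p["C"], G_leak=p["G_leak"], E_rest=p["E_rest"],
                    G_Na=p["G_Na"], E_Na=p["E_Na"],
                    m_gate=GatingParams(**p["m"]), h_gate=GatingParams(**p["h"]),
                ),
            ))
        synapses = [
            SynapseSpec(pre=s["pre"], post=s["post"], sign=s["sign"],
                        params=SynapseParams(**s["params"]))
            for s in raw.get("synapses", [])
        ]
        return cls(neurons=neurons, synapses=synapses, metadata=dict(raw.get("metadata", {})))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkSpec":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw)


# ---------------------------------------------------------------- helpers

def _syn_sign(syn: SynapseParams, post: NeuronParams) -> str:
    """A synapse is inhibitory iff its reversal sits at/below the postsynaptic rest."""
    return "inhibitory" if syn.E_syn <= post.E_rest else "excitatory"


def _connect(net: NetworkSpec, table: ParameterTable, cls: str,
             pre: str, post: str) -> None:
    """Add a synapse of class ``cls``; absent table rows omit the connection
    (recorded in metadata) rather than failing."""
    syn = table.synapse(cls)
    if syn is None:
        net.metadata.setdefault("omitted_connections", []).append(
            {"class": cls, "pre": pre, "post": post})
        return
    net.synapses.append(SynapseSpec(
        pre=pre, post=post, params=syn, sign=_syn_sign(syn, net.neuron(post).params)))


def compose(*parts: NetworkSpec, metadata: dict | None = None) -> NetworkSpec:
    """Union of neuron and synapse sets; duplicate neuron names are an error."""
    seen: set[str] = set()
    out = NetworkSpec(metadata=dict(metadata or {}))
    for part in parts:
        for n in part.neurons:
            if n.name in seen:
                raise NetworkError(f"duplicate neuron name {n.name!r} in composition")
            seen.add(n.name)
            out.neurons.append(n)
        out.synapses.extend(part.synapses)
        for key, val in part.metadata.items():
            if key == "omitted_connections":
                out.metadata.setdefault(key, []).extend(val)
    return out


def _half_center(table: ParameterTable, side: Side, joint: Joint, role: Role,
                 neuron_cls: str, in_joint: Joint | None = None) -> NetworkSpec:
    """Generic four-neuron half-center: two oscillator neurons with weak mutual
    excitation and crossed inhibition through two passive interneurons."""
    p = _SIDE_PREFIX[side]
    osc = table.neuron(neuron_cls)
    inter = table.neuron("IN")
    ij = in_joint if in_joint is not None else joint
    ext, flx = f"{p}_{joint}_{role}_EXT", f"{p}_{joint}_{role}_FLX"
    in_ext, in_flx = f"{p}_{ij}_IN_EXT", f"{p}_{ij}_IN_FLX"
    net = NetworkSpec(neurons=[
        NeuronSpec(ext, role, osc, side, joint, "extensor"),
        NeuronSpec(flx, role, osc, side, joint, "flexor"),
        NeuronSpec(in_ext, "IN", inter, side, ij, "extensor"),
        NeuronSpec(in_flx, "IN", inter, side, ij, "flexor"),
    ])
    _connect(net, table, f"{neuron_cls}->{neuron_cls}", ext, flx)
    _connect(net, table, f"{neuron_cls}->{neuron_cls}", flx, ext)
    _connect(net, table, f"{neuron_cls}->IN", ext, in_ext)
    _connect(net, table, f"{neuron_cls}->IN", flx, in_flx)
    _connect(net, table, f"IN->{neuron_cls}", in_ext, flx)
    _connect(net, table, f"IN->{neuron_cls}", in_flx, ext)
    return net


# ---------------------------------------------------------------- builders

def build_rhythm_generator(side: Side = "left",
                           table: ParameterTable | None = None) -> NetworkSpec:
    """Four-neuron half-center rhythm generator for one limb.

    Two persistent-sodium neurons (extensor/flexor) weakly excite each other
    directly and inhibit each other through dedicated interneurons; the pair
    oscillates endogenously and serves as the limb's step-cycle clock.
    """
    table = table or _default_table()
    net = _half_center(table, side, "limb", "RG", "RG")
    net.metadata.update({"topology": "rhythm_generator", "side": side})
    return net


def build_pattern_formation(joint: Joint, side: Side = "left",
                            table: ParameterTable | None = None) -> NetworkSpec:
    """Pattern-formation half-center for one joint group.

    ``joint`` is ``"hip"`` or ``"kneeankle"`` — the knee and ankle share one
    pattern formation network (muscle synergy).  The PF pair mutually inhibits
    via interneurons and accepts excitatory drive from the rhythm generator.
    """
    if joint not in ("hip", "kneeankle"):
        raise NetworkError(f"unknown pattern-formation joint {joint!r}; "
                           "expected 'hip' or 'kneeankle'")
    table = table or _default_table()
    net = _half_center(table, side, joint, "PF", "PF")
    net.metadata.update({"topology": "pattern_formation", "side": side, "joint": joint})
    return net


def build_motoneuron_layer(joint: Joint, side: Side = "left",
                           table: ParameterTable | None = None) -> NetworkSpec:
    """Extensor/flexor motoneurons with Renshaw-cell recurrent inhibition.

    PF->MN attachment points are simply the returned MN names.
    """
    table = table or _default_table()
    p = _SIDE_PREFIX[side]
    mn_p, re_p = table.neuron("MN"), table.neuron("RE")
    net = NetworkSpec(metadata={"topology": "motoneuron_layer", "side": side, "joint": joint})
    for pol, tag in (("extensor", "EXT"), ("flexor", "FLX")):
        mn, re = f"{p}_{joint}_MN_{tag}", f"{p}_{joint}_RE_{tag}"
        net.neurons.append(NeuronSpec(mn, "MN", mn_p, side, joint, pol))
        net.neurons.append(NeuronSpec(re, "RE", re_p, side, joint, pol))
        _connect(net, table, "MN->RE", mn, re)
        _connect(net, table, "RE->MN", re, mn)
    return net


def build_two_layer_chain(side: Side = "left", joint: Joint = "hip",
                          table: ParameterTable | None = None) -> NetworkSpec:
    """Deafferented validation chain: RG -> one PF group -> one MN pair.

    This is the isolated two-layer circuit used for rhythm-modulation and
    perturbation-memory experiments.
    """
    table = table or _default_table()
    rg = build_rhythm_generator(side, table)
    pf = build_pattern_formation(joint, side, table)
    mn = build_motoneuron_layer(joint, side, table)
    net = compose(rg, pf, mn, metadata={"topology": "two_layer_chain",
                                        "side": side, "joint": joint})
    _wire_rg_to_pf(net, table, side, joint)
    _wire_pf_to_mn(net, table, side, joint, joint)
    return net


def build_limb(side: Side = "left", table: ParameterTable | None = None) -> NetworkSpec:
    """Full single-limb hierarchy: RG, hip PF, shared knee-ankle PF, and six
    motoneurons (hip/knee/ankle x extensor/flexor) with Renshaw cells.

    The knee-ankle PF group projects to four motoneurons (knee and ankle pools
    both), implementing the fixed knee-ankle synergy.  Limbs are built fully
    independent: two limbs share no synapse.
    """
    table = table or _default_table()
    rg = build_rhythm_generator(side, table)
    pf_hip = build_pattern_formation("hip", side, table)
    pf_ka = build_pattern_formation("kneeankle", side, table)
    mns = [build_motoneuron_layer(j, side, table) for j in ("hip", "knee", "ankle")]
    net = compose(rg, pf_hip, pf_ka, *mns,
                  metadata={"topology": "limb", "side": side})
    _wire_rg_to_pf(net, table, side, "hip")
    _wire_rg_to_pf(net, table, side, "kneeankle")
    _wire_pf_to_mn(net, table, side, "hip", "hip")
    _wire_pf_to_mn(net, table, side, "kneeankle", "knee")
    _wire_pf_to_mn(net, table, side, "kneeankle", "ankle")
    return net


def build_single_joint_baseline(table: ParameterTable | None = None,
                                side: Side = "left") -> NetworkSpec:
    """Legacy single-layer circuit: a half-center synapsing directly onto
    motoneurons (no pattern-formation layer).

    In this architecture any perturbation of the half-center shifts step
    timing and motoneuron amplitude together, so stimuli reset the rhythm.
    """
    table = table or _default_table()
    hc = _half_center(table, side, "hip", "RG", "RG")
    mn = build_motoneuron_layer("hip", side, table)
    net = compose(hc, mn, metadata={"topology": "single_joint_baseline", "side": side})
    p = _SIDE_PREFIX[side]
    _connect(net, table, "HC->MN", f"{p}_hip_RG_EXT", f"{p}_hip_MN_EXT")
    _connect(net, table, "HC->MN", f"{p}_hip_RG_FLX", f"{p}_hip_MN_FLX")
    return net


def _wire_rg_to_pf(net: NetworkSpec, table: ParameterTable, side: Side, joint: Joint) -> None:
    # direct drive EXT->EXT / FLX->FLX, plus optional crossed drive through
    # the PF group's interneurons (RG EXT excites the PF IN that inhibits
    # PF FLX), which locks the PF half-center to the clock in both
    # directions of period modulation
    p = _SIDE_PREFIX[side]
    _connect(net, table, "RG->PF", f"{p}_limb_RG_EXT", f"{p}_{joint}_PF_EXT")
    _connect(net, table, "RG->PF", f"{p}_limb_RG_FLX", f"{p}_{joint}_PF_FLX")
    _connect(net, table, "RG->PFIN", f"{p}_limb_RG_EXT", f"{p}_{joint}_IN_EXT")
    _connect(net, table, "RG->PFIN", f"{p}_limb_RG_FLX", f"{p}_{joint}_IN_FLX")


def _wire_pf_to_mn(net: NetworkSpec, table: ParameterTable, side: Side,
                   pf_joint: Joint, mn_joint: Joint) -> None:
    p = _SIDE_PREFIX[side]
    _connect(net, table, "PF->MN", f"{p}_{pf_joint}_PF_EXT", f"{p}_{mn_joint}_MN_EXT")
    _connect(net, table, "PF->MN", f"{p}_{pf_joint}_PF_FLX", f"{p}_{mn_joint}_MN_FLX")


def _default_table() -> ParameterTable:
    from .params import default_parameter_table
    return default_parameter_table()


# -------------------------------------------------------------- validation

@dataclass(frozen=True)
class Diagnostic:
    severity: Literal["error", "warning"]
    message: str


def validate_network(net: NetworkSpec) -> list[Diagnostic]:
    """Structural diagnostics; an empty list means the network is valid.

    Checks: duplicate neuron names, dangling synapse endpoints, self-synapses,
    sign/reversal-potential inconsistencies, and persistent sodium on
    interneuron-class cells (warning).
    """
    out: list[Diagnostic] = []
    names: set[str] = set()
    for n in net.neurons:
        if n.name in names:
            out.append(Diagnostic("error", f"duplicate neuron name {n.name!r}"))
        names.add(n.name)
        if n.role in ("IN", "RE", "MN") and n.params.G_Na > 0:
            out.append(Diagnostic(
                "warning", f"{n.role} neuron {n.name!r} has G_Na > 0; "
                "interneuron-class cells should be passive"))
        if n.role in ("RG", "PF") and n.params.G_Na <= 0:
            out.append(Diagnostic(
                "warning", f"oscillator neuron {n.name!r} has no persistent sodium"))
    by_name = {n.name: n for n in net.neurons}
    for s in net.synapses:
        for end, label in ((s.pre, "pre"), (s.post, "post")):
            if end not in names:
                out.append(Diagnostic("error", f"synapse {s.pre}->{s.post}: "
                                               f"unknown {label} neuron {end!r}"))
        if s.post in by_name:
            expect = _syn_sign(s.params, by_name[s.post].params)
            if expect != s.sign:
                out.append(Diagnostic(
                    "error", f"synapse {s.pre}->{s.post} labeled {s.sign} but "
                             f"E_syn={s.params.E_syn} mV is {expect} for this target"))
    return out
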