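"""Parameter tables: typed neuron/synapse parameter sets loaded from YAML.

A parameter table supplies the electrical constants for every neuron *class*
(RG, PF, MN, IN, RE) and every synapse *class* (``"RG->IN"``, ``"IN->RG"``,
...), together with a units declaration.  Network builders resolve concrete
neurons and synapses against these classes, so the whole circuit is tuned by
editing one small text file.

The packaged default table (``data/default_params.yaml``) is the calibrated
operating point of the two-layer locomotor CPG: with it, the deafferented
rhythm generator + pattern formation chain produces a 0.5 s stride that
shortens to ~0.35 s under +2 nA descending drive and lengthens to ~0.65 s
under -2 nA.  A second "overlay" file may be layered on top to retune
without editing the base table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import GatingParams, NeuronParams, SynapseParams, INERT_GATE

__all__ = ["ParameterTable", "ParameterTableError", "load_parameter_table", "default_parameter_table"]

# The fixed unit system; tables must declare exactly these.
EXPECTED_UNITS = {
    "voltage": "mV",
    "time": "ms",
    "current": "nA",
    "conductance": "uS",
    "capacitance": "nF",
}

_NEURON_KEYS = {"C", "G_leak", "E_rest", "G_Na", "E_Na", "m", "h"}
_GATE_KEYS = {"A", "S", "E_half", "tau", "tau_voltage_dependent"}
_GATE_REQUIRED = {"A", "S", "E_half", "tau"}
_SYNAPSE_KEYS = {"g_max", "E_syn", "E_lo", "E_hi"}


class ParameterTableError(ValueError):
    """Schema violation in a parameter table, with row/column location."""


@dataclass
class ParameterTable:
    """Typed, unit-checked neuron and synapse parameter classes."""

    neurons: dict[str, NeuronParams]
    synapses: dict[str, SynapseParams]
    units: dict[str, str] = field(default_factory=lambda: dict(EXPECTED_UNITS))
    source: str = "<memory>"

    def neuron(self, cls: str) -> NeuronParams:
        try:
            return self.neurons[cls]
        except KeyError:
            raise ParameterTableError(
                f"no neuron class {cls!r} in parameter table {self.source}"
            ) from None

    def synapse(self, cls: str) -> SynapseParams | None:
        """Synapse class lookup; absent classes return None (connection omitted)."""
        return self.synapses.get(cls)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"units": dict(self.units), "neurons": {}, "synapses": {}}
        for name, p in self.neurons.items():
            row: dict[str, Any] = {
                "C": p.C, "G_leak": p.G_leak, "E_rest": p.E_rest,
                "G_Na": p.G_Na, "E_Na": p.E_Na,
            }
            if p.G_Na > 0:
                for col, gate in (("m", p.m_gate), ("h", p.h_gate)):
                    row[col] = {"A": gate.A, "S": gate.S,
                                "E_half": gate.E_half, "tau": gate.tau}
                    if gate.tau_voltage_dependent:
                        row[col]["tau_voltage_dependent"] = True
            out["neurons"][name] = row
        for name, s in self.synapses.items():
            out["synapses"][name] = {"g_max": s.g_max, "E_syn": s.E_syn,
                                     "E_lo": s.E_lo, "E_hi": s.E_hi}
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _parse_gate(raw: Mapping[str, Any], where: str) -> GatingParams:
    unknown = set(raw) - _GATE_KEYS
    if unknown:
        raise ParameterTableError(f"{where}: unknown gate column(s) {sorted(unknown)}")
    missing = _GATE_REQUIRED - set(raw)
    if missing:
        raise ParameterTableError(f"{where}: missing gate column(s) {sorted(missing)}")
    try:
        return GatingParams(A=float(raw["A"]), S=float(raw["S"]),
                            E_half=float(raw["E_half"]), tau=float(raw["tau"]),
                            tau_voltage_dependent=bool(raw.get("tau_voltage_dependent", False)))
    except ValueError as e:
        raise ParameterTableError(f"{where}: {e}") from None


def _parse_neuron(name: str, raw: Mapping[str, Any]) -> NeuronParams:
    where = f"neuron row {name!r}"
    if not isinstance(raw, Mapping):
        raise ParameterTableError(f"{where}: expected a mapping")
    unknown = set(raw) - _NEURON_KEYS
    if unknown:
        raise ParameterTableError(f"{where}: unknown column(s) {sorted(unknown)}")
    for col in ("C", "G_leak", "E_rest"):
        if col not in raw:
            raise ParameterTableError(f"{where}: missing column {col!r}")
    g_na = float(raw.get("G_Na", 0.0))
    if g_na > 0:
        for col in ("m", "h"):
            if col not in raw:
                raise ParameterTableError(f"{where}: G_Na > 0 but missing gate block {col!r}")
        m = _parse_gate(raw["m"], f"{where}, gate 'm'")
        h = _parse_gate(raw["h"], f"{where}, gate 'h'")
    else:
        m = h = INERT_GATE
    try:
        return NeuronParams(C=float(raw["C"]), G_leak=float(raw["G_leak"]),
                            E_rest=float(raw["E_rest"]), G_Na=g_na,
                            E_Na=float(raw.get("E_Na", 50.0)), m_gate=m, h_gate=h)
    except ValueError as e:
        raise ParameterTableError(f"{where}: {e}") from None


def _parse_synapse(name: str, raw: Mapping[str, Any]) -> SynapseParams:
    where = f"synapse row {name!r}"
    if not isinstance(raw, Mapping):
        raise ParameterTableError(f"{where}: expected a mapping")
    unknown = set(raw) - _SYNAPSE_KEYS
    if unknown:
        raise ParameterTableError(f"{where}: unknown column(s) {sorted(unknown)}")
    missing = _SYNAPSE_KEYS - set(raw)
    if missing:
        raise ParameterTableError(f"{where}: missing column(s) {sorted(missing)}")
    try:
        return SynapseParams(g_max=float(raw["g_max"]), E_syn=float(raw["E_syn"]),
                             E_lo=float(raw["E_lo"]), E_hi=float(raw["E_hi"]))
    except ValueError as e:
        raise ParameterTableError(f"{where}: {e}") from None


def _deep_merge(base: dict, overlay: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in overlay.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _from_raw(raw: Mapping[str, Any], source: str) -> ParameterTable:
    unknown = set(raw) - {"units", "neurons", "synapses"}
    if unknown:
        raise ParameterTableError(f"{source}: unknown top-level key(s) {sorted(unknown)}")
    units = dict(raw.get("units", {}))
    if units != EXPECTED_UNITS:
        raise ParameterTableError(
            f"{source}: units block must declare exactly {EXPECTED_UNITS}, got {units}"
        )
    neurons = {str(k): _parse_neuron(str(k), v) for k, v in dict(raw.get("neurons", {})).items()}
    synapses = {str(k): _parse_synapse(str(k), v) for k, v in dict(raw.get("synapses", {})).items()}
    if not neurons:
        raise ParameterTableError(f"{source}: table declares no neuron rows")
    return ParameterTable(neurons=neurons, synapses=synapses, units=units, source=source)


def load_parameter_table(path: str | Path, overlay: str | Path | None = None) -> ParameterTable:
    """Load a YAML parameter table, optionally merged with a tuning overlay.

    The overlay is a YAML file of the same shape whose entries override the
    base table field-by-field; it is the sanctioned place for retuning.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ParameterTableError(f"{path}: top level must be a mapping")
    raw = dict(raw)
    source = str(path)
    if overlay is not None:
        overlay = Path(overlay)
        raw_ov = yaml.safe_load(overlay.read_text())
        if raw_ov:
            if not isinstance(raw_ov, Mapping):
                raise ParameterTableError(f"{overlay}: top level must be a mapping")
            raw = _deep_merge(raw, raw_ov)
            source = f"{path}+{overlay}"
    return _from_raw(raw, source)


def default_parameter_table() -> ParameterTable:
    """The packaged, calibrated default table."""
    ref = resources.files("cpgnet.data").joinpath("default_params.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _from_raw(raw, "cpgnet.data/default_params.yaml")
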