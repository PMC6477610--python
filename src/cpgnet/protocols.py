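"""Canned experiments: drive modulation, perturbation memory, deletions.

Each experiment builds (or accepts) a network, runs the documented stimulus
protocol together with an unperturbed reference sharing every other setting,
and returns traces plus the cycle/phase analyses.  All experiments are
deterministic and reproducible bit-exactly from their provenance.

The deafferented protocols operate on the two-layer chain (rhythm generator
-> one pattern-formation group -> one motoneuron pair); step cycles are
measured on the extensor pattern-formation neuron's rising -60 mV crossings,
after blanking the 0.5 s startup transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkSpec, build_limb, build_single_joint_baseline, build_two_layer_chain
from .params import ParameterTable
from .rhythm import (BurstReport, CycleReport, ResetReport, burst_bounds,
                     detect_cycles, period_in_window, phase_shift)
from .simulate import SimulationConfig, StimulusProtocol, TraceSet, run, startup_kick

__all__ = ["ExperimentResult", "mlr_drive_experiment", "pf_memory_experiment",
           "deletion_experiment", "baseline_perturbation_experiment",
           "MN_BURST_THRESHOLD"]

# Motoneuron burst threshold (mV).  The cycle threshold (-60 mV) sits at the
# MN resting potential, which motoneurons approach from above between bursts;
# bursts are therefore delimited slightly depolarized from rest.
MN_BURST_THRESHOLD = -55.0


@dataclass
class ExperimentResult:
    traces: TraceSet
    reference_traces: TraceSet | None
    cycles: CycleReport
    reference_cycles: CycleReport | None
    epochs: pd.DataFrame | None = None
    reset: ResetReport | None = None
    bursts: BurstReport | None = None
    extras: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _pf_ext_name(net: NetworkSpec) -> str:
    names = net.find(role="PF", polarity="extensor")
    if not names:
        # single-layer baseline: fall back to the half-center extensor
        names = net.find(role="RG", polarity="extensor")
    if not names:
        raise ValueError("network has no extensor oscillator neuron to analyze")
    return names[0]


def _epoch_table(report: CycleReport, epochs: list[tuple[float, float]]) -> pd.DataFrame:
    rows = []
    for t0, t1 in epochs:
        mean, sd, n = report.mean_period(t0, t1)
        c = report.crossings
        keep = (c[:-1] >= t0) & (c[1:] <= t1)
        rows.append({"t_start": t0, "t_end": t1, "mean_period_s": mean,
                     "sd_period_s": sd, "n_cycles": n,
                     "periods_s": report.periods[keep].tolist()})
    return pd.DataFrame(rows)


def mlr_drive_experiment(net: NetworkSpec | None = None,
                         config: SimulationConfig | None = None,
                         amplitude: float = 2.0,
                         table: ParameterTable | None = None) -> ExperimentResult:
    """Tonic descending-drive modulation of the step rhythm.

    Simulates midbrain-locomotor-region drive: ``+amplitude`` nA into both
    rhythm-generator neurons from 1.5-2.5 s and ``-amplitude`` from
    3.5-4.5 s.  Positive drive shortens the stride period, negative drive
    lengthens it, and the period returns to baseline between and after the
    stimuli.  Reports the per-epoch period table for epochs
    [0.5,1.5], [1.5,2.5], [2.5,3.5], [3.5,4.5], [4.5,end].
    """
    net = net if net is not None else build_two_layer_chain(table=table)
    config = config or SimulationConfig(duration=5.5)
    rg = sorted(net.find(role="RG"))
    if len(rg) != 2:
        raise ValueError(f"expected one extensor/flexor RG pair, found {rg}")
    stimuli = [startup_kick(net)]
    for name in rg:
        stimuli.append(StimulusProtocol(name, amplitude, 1.5, 2.5))
        stimuli.append(StimulusProtocol(name, -amplitude, 3.5, 4.5))
    traces = run(net, stimuli, config=config)
    pf_ext = _pf_ext_name(net)
    cycles = detect_cycles(traces.time, traces[pf_ext],
                           t_start=config.startup_transient_blank)
    epochs = [(0.5, 1.5), (1.5, 2.5), (2.5, 3.5), (3.5, 4.5), (4.5, config.duration)]
    flx = net.find(role="PF", polarity="flexor")
    extras = {}
    if flx:
        extras["flexor_cycles"] = detect_cycles(
            traces.time, traces[flx[0]], t_start=config.startup_transient_blank)
    return ExperimentResult(
        traces=traces, reference_traces=None, cycles=cycles, reference_cycles=None,
        epochs=_epoch_table(cycles, epochs), extras=extras,
        provenance={"experiment": "mlr_drive", "amplitude_nA": amplitude,
                    "measured_neuron": pf_ext, "epochs": epochs,
                    **traces.provenance})


def pf_memory_experiment(net: NetworkSpec | None = None,
                         config: SimulationConfig | None = None,
                         amplitude: float = 2.0,
                         short_anchor: float = 1.0,
                         short_duration: float = 0.1,
                         long_window: tuple[float, float] = (2.5, 3.5),
                         align_short: bool = True,
                         table: ParameterTable | None = None) -> ExperimentResult:
    """Perturbation "memory" of the two-layer circuit.

    Two excitatory stimuli to the extensor pattern-formation neuron: one
    shorter than a step cycle (0.1 s, near 1 s) and one longer (default
    2.5-3.5 s).  The short stimulus advances the flexor-to-extensor phase
    switch within the ongoing cycle — the extensor period containing it is
    shortened and the following flexor period lengthened — without moving
    later cycle onsets.  The long one deletes motoneuron bursts while the
    rhythm-generator clock keeps running, so post-stimulus bursts reappear
    at the predicted phase (a non-resetting deletion).

    The within-cycle effect depends on where in the cycle the pulse lands,
    and the cycle phase at any wall-clock instant is a calibration detail;
    with ``align_short`` (default) the pulse is placed so it ends at the
    first flexor-to-extensor transition of the unperturbed reference after
    ``short_anchor``, i.e. in late flexion, the phase the published
    perturbation occupies.  The actual window used is recorded in the
    provenance.
    """
    net = net if net is not None else build_two_layer_chain(table=table)
    config = config or SimulationConfig(duration=5.0)
    pf_ext = _pf_ext_name(net)
    pf_flx = net.find(role="PF", polarity="flexor")[0]
    kick = startup_kick(net)
    ref_traces = run(net, [kick], config=config)
    blank = config.startup_transient_blank
    ref_cycles = detect_cycles(ref_traces.time, ref_traces[pf_ext], t_start=blank)

    if align_short:
        nxt = ref_cycles.crossings[ref_cycles.crossings >= short_anchor]
        if nxt.size == 0:
            raise ValueError("no reference extensor onset after the short-stimulus anchor")
        short_window = (float(nxt[0]) - short_duration, float(nxt[0]))
    else:
        short_window = (short_anchor, short_anchor + short_duration)

    stimuli = [kick,
               StimulusProtocol(pf_ext, amplitude, *short_window),
               StimulusProtocol(pf_ext, amplitude, *long_window)]
    traces = run(net, stimuli, config=config)
    cycles = detect_cycles(traces.time, traces[pf_ext], t_start=blank)

    # short stimulus: following-cycle onsets vs reference, restricted to
    # before the long stimulus
    upto = long_window[0]
    short_reset = phase_shift(
        CycleReport(ref_cycles.crossings[ref_cycles.crossings < upto], cycles.threshold),
        CycleReport(cycles.crossings[cycles.crossings < upto], cycles.threshold),
        short_window)
    long_reset = phase_shift(ref_cycles, cycles, long_window)

    # within-cycle redistribution: the extensor period whose crossings
    # bracket the stimulus onset, and the first flexor period beginning
    # after it, each against the same-position reference period
    flx_cycles = detect_cycles(traces.time, traces[pf_flx], t_start=blank)
    ref_flx_cycles = detect_cycles(ref_traces.time, ref_traces[pf_flx], t_start=blank)

    def _bracketing(rep: CycleReport, t: float) -> float:
        c = rep.crossings
        i = int(np.searchsorted(c, t)) - 1
        if i < 0 or i + 1 >= len(c):
            return float("nan")
        return float(c[i + 1] - c[i])

    def _first_after(rep: CycleReport, t: float) -> float:
        c = rep.crossings
        i = int(np.searchsorted(c, t))
        if i + 1 >= len(c):
            return float("nan")
        return float(c[i + 1] - c[i])

    t_on = short_window[0]
    ext_p, ext_r = _bracketing(cycles, t_on), _bracketing(ref_cycles, t_on)
    flx_p, flx_r = _first_after(flx_cycles, t_on), _first_after(ref_flx_cycles, t_on)

    mn_ext = net.find(role="MN", polarity="extensor")
    bursts = None
    if mn_ext:
        bursts = burst_bounds(traces.time, traces[mn_ext[0]],
                              MN_BURST_THRESHOLD, t_start=blank)
    return ExperimentResult(
        traces=traces, reference_traces=ref_traces, cycles=cycles,
        reference_cycles=ref_cycles, reset=long_reset, bursts=bursts,
        extras={"short_reset": short_reset,
                "ext_period_s": ext_p, "flx_period_s": flx_p,
                "ext_period_ref_s": ext_r, "flx_period_ref_s": flx_r},
        provenance={"experiment": "pf_memory", "amplitude_nA": amplitude,
                    "short_window_s": short_window, "long_window_s": long_window,
                    "measured_neuron": pf_ext, **traces.provenance})


def deletion_experiment(net: NetworkSpec | None = None,
                        layer: str = "PF",
                        config: SimulationConfig | None = None,
                        amplitude: float = -10.0,
                        anchor: float = 2.0,
                        duration: float = 0.1,
                        align: bool = True,
                        side: str = "left",
                        table: ParameterTable | None = None) -> ExperimentResult:
    """Inhibitory deletion stimulus at the PF or RG layer.

    Defaults follow the deletion protocol: -10 nA for 0.1 s near 2 s into
    the hip extensor pattern-formation neuron (``layer="PF"``; non-resetting
    in the deafferented circuit) or the extensor rhythm-generator neuron
    (``layer="RG"``; resetting — the clock itself is perturbed).

    The pulse must interrupt ongoing extensor activity to test anything;
    with ``align`` (default) its onset is placed at the first extensor-phase
    onset of the unperturbed reference at/after ``anchor``, since the cycle
    phase at a given wall-clock time is a calibration detail.  The window
    actually used is recorded in the provenance.
    """
    net = net if net is not None else build_limb(side=side, table=table)
    config = config or SimulationConfig(duration=5.0)
    if layer == "PF":
        targets = net.find(role="PF", side=side, joint="hip", polarity="extensor") or \
            net.find(role="PF", side=side, polarity="extensor")
    elif layer == "RG":
        targets = net.find(role="RG", side=side, polarity="extensor")
    else:
        raise ValueError(f"unknown layer {layer!r}; expected 'PF' or 'RG'")
    if not targets:
        raise ValueError(f"no {layer} extensor target on side {side!r}")
    target = targets[0]
    kick = startup_kick(net, side=side)
    ref_traces = run(net, [kick], config=config)
    blank = config.startup_transient_blank
    pf_ext = _pf_ext_name(net)
    ref_cycles = detect_cycles(ref_traces.time, ref_traces[pf_ext], t_start=blank)
    if align:
        nxt = ref_cycles.crossings[ref_cycles.crossings >= anchor]
        if nxt.size == 0:
            raise ValueError("no reference extensor onset after the deletion anchor")
        window = (float(nxt[0]), float(nxt[0]) + duration)
    else:
        window = (anchor, anchor + duration)
    stim = StimulusProtocol(target, amplitude, *window)
    traces = run(net, [kick, stim], config=config)
    cycles = detect_cycles(traces.time, traces[pf_ext], t_start=blank)
    reset = phase_shift(ref_cycles, cycles, window)
    mn_ext = net.find(role="MN", side=side, joint="hip", polarity="extensor") or \
        net.find(role="MN", side=side, polarity="extensor")
    bursts = burst_bounds(traces.time, traces[mn_ext[0]],
                          MN_BURST_THRESHOLD, t_start=blank) if mn_ext else None
    return ExperimentResult(
        traces=traces, reference_traces=ref_traces, cycles=cycles,
        reference_cycles=ref_cycles, reset=reset, bursts=bursts,
        provenance={"experiment": "deletion", "layer": layer, "target": target,
                    "amplitude_nA": amplitude, "window_s": window,
                    "measured_neuron": pf_ext, **traces.provenance})


def baseline_perturbation_experiment(net: NetworkSpec | None = None,
                                     config: SimulationConfig | None = None,
                                     amplitude: float = 2.0,
                                     window: tuple[float, float] = (2.0, 2.1),
                                     table: ParameterTable | None = None) -> ExperimentResult:
    """Excitatory pulse to the legacy single-layer half-center.

    With the half-center synapsing directly onto motoneurons, a +2 nA pulse
    (2-2.1 s) to the extensor half-center neuron shifts every subsequent
    cycle onset: the perturbation is resetting, which is exactly the
    limitation the two-layer architecture removes.
    """
    net = net if net is not None else build_single_joint_baseline(table=table)
    config = config or SimulationConfig(duration=5.0)
    hc_ext = net.find(role="RG", polarity="extensor")[0]
    kick = StimulusProtocol(hc_ext, 2.0, 0.0, 0.5)
    stim = StimulusProtocol(hc_ext, amplitude, *window)
    traces = run(net, [kick, stim], config=config)
    ref_traces = run(net, [kick], config=config)
    blank = config.startup_transient_blank
    cycles = detect_cycles(traces.time, traces[hc_ext], t_start=blank)
    ref_cycles = detect_cycles(ref_traces.time, ref_traces[hc_ext], t_start=blank)
    reset = phase_shift(ref_cycles, cycles, window)
    return ExperimentResult(
        traces=traces, reference_traces=ref_traces, cycles=cycles,
        reference_cycles=ref_cycles, reset=reset,
        provenance={"experiment": "baseline_perturbation", "target": hc_ext,
                    "amplitude_nA": amplitude, "window_s": window,
                    **traces.provenance})
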