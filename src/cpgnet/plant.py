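"""A deliberately minimal mechanical load and afferent loop.

This is an explicit stand-in: one rotational degree of freedom per
pattern-formation group (hip; knee-ankle lumped), driven by an antagonistic
pair of first-order "muscles", with linear clamped afferent feedback.  Its
only job is to close the sensorimotor loop plausibly so closed-loop
phenomena (slow post-perturbation rhythm recovery, mechanical entrainment)
can be demonstrated; it is not a biomechanically calibrated body, and all
of its equations are stand-ins.

Mechanics per joint (semi-implicit Euler):

    torque = gain * (act_ext - act_flx) - damping * omega - stiffness * angle
    domega/dt = torque / inertia;  dangle/dt = omega

Muscle activation is a first-order low-pass of a saturating piecewise-linear
map of motoneuron voltage.  Afferents are linear with clamps: a velocity-
proportional (Ia-like), a position-proportional (II-like), and an
extensor-torque-proportional (Ib-like) current, each routed to configured
neurons.  Zero gains decouple the plant exactly: the closed-loop trace is
then bit-identical to the deafferented run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import NetworkSpec
from .simulate import (CompiledNetwork, NoiseSpec, SimulationConfig,
                       SimulationError, StimulusProtocol, TraceSet, run)

__all__ = ["JointState", "PlantParams", "AfferentRoute", "muscle_activation",
           "plant_step", "afferent_currents", "run_closed_loop",
           "default_limb_joints", "default_afferent_routes"]


@dataclass
class JointState:
    angle: float = 0.0  # rad
    omega: float = 0.0  # rad/s
    act_ext: float = 0.0  # muscle activations, fraction
    act_flx: float = 0.0


@dataclass(frozen=True)
class AfferentRoute:
    """Route one afferent modality of one joint to one neuron."""

    modality: str  # "Ia" | "II" | "Ib"
    joint: str  # plant joint name
    target: str  # neuron name
    gain: float  # nA per rad/s (Ia), per rad (II), per torque unit (Ib)


@dataclass(frozen=True)
class PlantParams:
    """One-DOF joint + muscle-pair constants (stand-in values).

    The elastic ``stiffness`` term acts as a soft joint limit / passive
    tissue restoring force; it also gives the joint a well-defined steady
    angle under constant activation.
    """

    inertia: float = 0.01  # kg m^2 equivalents
    damping: float = 0.05  # torque per rad/s
    stiffness: float = 0.5  # torque per rad
    muscle_gain: float = 1.0  # torque per unit activation
    act_tau: float = 30.0  # muscle activation time constant, ms
    v_lo: float = -60.0  # MN voltage mapping to activation 0, mV
    v_hi: float = -40.0  # MN voltage mapping to activation 1, mV
    i_max: float = 10.0  # clamp on each afferent current, nA
    routes: tuple[AfferentRoute, ...] = ()

    def __post_init__(self) -> None:
        if not self.inertia > 0:
            raise ValueError("inertia must be positive")
        if self.damping < 0 or self.stiffness < 0:
            raise ValueError("damping and stiffness must be non-negative")
        if not self.act_tau > 0:
            raise ValueError("activation time constant must be positive")


def muscle_activation(V_mn: float, act: float, params: PlantParams, dt: float) -> float:
    """Advance one muscle's activation one step of ``dt`` ms.

    First-order low-pass (exact exponential update) of a clamped linear map
    of motoneuron voltage; output stays in [0, 1] for any input.
    """
    target = min(max((V_mn - params.v_lo) / (params.v_hi - params.v_lo), 0.0), 1.0)
    a = target + (act - target) * np.exp(-dt / params.act_tau)
    return float(min(max(a, 0.0), 1.0))


def plant_step(state: JointState, params: PlantParams, dt: float) -> tuple[JointState, float]:
    """Advance the joint one step of ``dt`` ms; returns (new state, torque).

    Semi-implicit Euler: velocity first, then position with the new velocity.
    """
    torque = (params.muscle_gain * (state.act_ext - state.act_flx)
              - params.damping * state.omega - params.stiffness * state.angle)
    dt_s = dt / 1000.0
    omega = state.omega + dt_s * torque / params.inertia
    angle = state.angle + dt_s * omega
    if not (np.isfinite(angle) and np.isfinite(omega)):
        raise SimulationError("plant state diverged")
    return JointState(angle=angle, omega=omega,
                      act_ext=state.act_ext, act_flx=state.act_flx), torque


def afferent_currents(joints: dict[str, JointState], torques: dict[str, float],
                      params: PlantParams) -> dict[str, float]:
    """Per-target afferent currents in nA.

    Ia-like: proportional to joint angular velocity; II-like: to joint angle;
    Ib-like: to (positive part of) extensor torque.  Each contribution is
    clamped to +/- ``i_max``.  All-zero gains give an empty/zero map.
    """
    out: dict[str, float] = {}
    for r in params.routes:
        if r.joint not in joints:
            raise KeyError(f"afferent route references unknown joint {r.joint!r}")
        st = joints[r.joint]
        if r.modality == "Ia":
            val = r.gain * st.omega
        elif r.modality == "II":
            val = r.gain * st.angle
        elif r.modality == "Ib":
            val = r.gain * max(torques.get(r.joint, 0.0), 0.0)
        else:
            raise ValueError(f"unknown afferent modality {r.modality!r}")
        val = min(max(val, -params.i_max), params.i_max)
        out[r.target] = out.get(r.target, 0.0) + val
    return out


def default_limb_joints(side: str = "left") -> dict[str, tuple[str, str]]:
    """One rotational DOF per pattern-formation group: the hip joint driven
    by the hip MN pair, and a lumped knee-ankle joint driven (as a stand-in)
    by the knee MN pair."""
    p = {"left": "L", "right": "R"}[side]
    return {"hip": (f"{p}_hip_MN_EXT", f"{p}_hip_MN_FLX"),
            "kneeankle": (f"{p}_knee_MN_EXT", f"{p}_knee_MN_FLX")}


def default_afferent_routes(side: str = "left", g_II: float = 6.0,
                            g_Ib: float = 4.0) -> tuple[AfferentRoute, ...]:
    """Demonstration feedback routing: hip position (II-like) steers the
    rhythm-generator half-center toward phase switching, and lumped extensor
    load (Ib-like) reinforces extension — enough coupling for the plant's
    state to re-enter the clock.  Gains are stand-in values in nA per rad
    (II) / per torque unit (Ib)."""
    p = {"left": "L", "right": "R"}[side]
    return (AfferentRoute("II", "hip", f"{p}_limb_RG_FLX", g_II),
            AfferentRoute("II", "hip", f"{p}_limb_RG_EXT", -g_II),
            AfferentRoute("Ib", "kneeankle", f"{p}_limb_RG_EXT", g_Ib))


def run_closed_loop(net: NetworkSpec, plant: PlantParams,
                    joints: dict[str, tuple[str, str]],
                    stimuli: Sequence[StimulusProtocol] = (),
                    noise: NoiseSpec | None = None,
                    config: SimulationConfig = SimulationConfig()) -> tuple[TraceSet, dict[str, np.ndarray]]:
    """Integrate network and plant together.

    ``joints`` maps a joint name to its (extensor MN, flexor MN) neuron
    names.  Returns the TraceSet plus per-joint angle arrays on the same
    time grid.  With all afferent gains zero the TraceSet is bit-identical
    to the corresponding deafferented :func:`run`.
    """
    comp = CompiledNetwork(net)
    for jn, (ext, flx) in joints.items():
        for name in (ext, flx):
            if name not in comp.index:
                raise SimulationError(f"joint {jn!r} references unknown neuron {name!r}")
    for r in plant.routes:
        if r.target not in comp.index:
            raise SimulationError(f"afferent route targets unknown neuron {r.target!r}")

    state = {jn: JointState() for jn in joints}
    torques = {jn: 0.0 for jn in joints}
    n_steps = int(round(config.duration * 1000.0 / config.dt))
    angles = {jn: np.empty(n_steps + 1) for jn in joints}
    for jn in joints:
        angles[jn][0] = 0.0
    idx = {jn: (comp.index[e], comp.index[f]) for jn, (e, f) in joints.items()}
    target_idx = {r.target: comp.index[r.target] for r in plant.routes}

    def hook(k: int, I_ext: np.ndarray, V: np.ndarray) -> None:
        # advance the plant with the voltages at the start of this step,
        # then inject the resulting afferent currents into the same step
        for jn in joints:
            i_ext, i_flx = idx[jn]
            st = state[jn]
            st = JointState(angle=st.angle, omega=st.omega,
                            act_ext=muscle_activation(V[i_ext], st.act_ext, plant, config.dt),
                            act_flx=muscle_activation(V[i_flx], st.act_flx, plant, config.dt))
            st, tq = plant_step(st, plant, config.dt)
            state[jn], torques[jn] = st, tq
            angles[jn][k + 1] = st.angle
        if plant.routes:
            for tgt, cur in afferent_currents(state, torques, plant).items():
                I_ext[target_idx[tgt]] += cur

    traces = run(comp, stimuli, noise, config, extra_current=hook)
    traces.provenance["plant"] = {
        "joints": {jn: list(pair) for jn, pair in joints.items()},
        "routes": [{"modality": r.modality, "joint": r.joint,
                    "target": r.target, "gain": r.gain} for r in plant.routes],
    }
    return traces, angles
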