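"""Membrane and synapse dynamics for non-spiking leaky-integrator neurons.

Every neuron obeys a single first-order membrane equation with a leak
conductance, graded synaptic conductances, an optional persistent sodium
current with activation/inactivation gates ``m`` and ``h``, and an applied
current:

    C dV/dt = G_leak (E_rest - V) + sum_i g_i (E_syn,i - V)
              + G_Na m h (E_Na - V) + I_app

Gates relax first-order toward a sigmoidal steady state:

    dz/dt = (z_inf(V) - z) / tau_z,   z_inf = 1 / (1 + A exp(S (V - E)))

and synapses are graded (non-spiking): the conductance is a piecewise-linear
saturating function of the presynaptic voltage between a lower and an upper
threshold.

Units are fixed package-wide: mV, ms, nA, uS, nF.  With these units the
membrane equation is dimensionally consistent without conversion factors
(uS * mV = nA, nA / nF = mV/ms).

Everything in this module is a pure function of explicit parameter objects;
network topology and time stepping live elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GatingParams",
    "NeuronParams",
    "SynapseParams",
    "NeuronState",
    "gating_steady_state",
    "gating_time_constant",
    "gating_derivative",
    "synaptic_conductance",
    "membrane_derivative",
]


@dataclass(frozen=True)
class GatingParams:
    """Sigmoid + relaxation constants for one gating variable (m or h).

    Parameters
    ----------
    A : float
        Dimensionless sigmoid factor.  ``A = 0`` pins the steady state at 1
        (used for the inert placeholder gates of passive neurons).
    S : float
        Sigmoid slope in 1/mV.  Negative slope gives a steady state that
        increases with voltage (activation), positive slope a decreasing one
        (inactivation).
    E_half : float
        Reference voltage of the sigmoid, mV.
    tau : float
        Relaxation time constant, ms.  Must be positive.  With
        ``tau_voltage_dependent`` this is the scale ``tau_max`` of the
        standard bell-shaped persistent-sodium kinetics

            tau(V) = tau_max * z_inf(V) * sqrt(A * exp(S (V - E_half)))

        which peaks where ``z_inf = 0.5`` and becomes fast at both voltage
        extremes — in particular, inactivation speeds up strongly with
        depolarization, giving activity-dependent burst adaptation.
    tau_voltage_dependent : bool
        Select the voltage-dependent kinetics above (requires ``A > 0``).
        Default is a constant time constant.
    """

    A: float
    S: float
    E_half: float
    tau: float
    tau_voltage_dependent: bool = False

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"gate time constant must be positive, got {self.tau}")
        if self.A < 0:
            raise ValueError(f"gate factor A must be non-negative, got {self.A}")
        if self.tau_voltage_dependent and self.A == 0:
            raise ValueError("voltage-dependent tau requires A > 0")


# Placeholder gate for passive neurons: G_Na = 0 makes the sodium term
# identically zero, so these values are inert but keep tau valid.
INERT_GATE = GatingParams(A=0.0, S=0.0, E_half=0.0, tau=1.0)


@dataclass(frozen=True)
class NeuronParams:
    """Electrical parameters of one leaky-integrator neuron.

    Interneurons (and any other passive cell) are represented with the same
    type with ``G_Na = 0`` and inert gate parameters.
    """

    C: float  # membrane capacitance, nF
    G_leak: float  # leak conductance, uS
    E_rest: float  # resting potential, mV
    G_Na: float = 0.0  # persistent sodium max conductance, uS
    E_Na: float = 50.0  # sodium reversal potential, mV
    m_gate: GatingParams = field(default=INERT_GATE)
    h_gate: GatingParams = field(default=INERT_GATE)

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"capacitance must be positive, got {self.C}")
        if not self.G_leak > 0:
            raise ValueError(f"leak conductance must be positive, got {self.G_leak}")
        if self.G_Na < 0:
            raise ValueError(f"G_Na must be non-negative, got {self.G_Na}")

    @property
    def is_passive(self) -> bool:
        return self.G_Na == 0.0


@dataclass(frozen=True)
class SynapseParams:
    """Graded (non-spiking) synapse constants.

    The conductance ramps linearly from 0 at presynaptic voltage ``E_lo`` to
    ``g_max`` at ``E_hi`` and saturates outside that range.
    """

    g_max: float  # maximal conductance, uS
    E_syn: float  # synaptic reversal potential, mV
    E_lo: float  # lower presynaptic threshold, mV
    E_hi: float  # upper presynaptic threshold, mV

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError(f"g_max must be non-negative, got {self.g_max}")
        if not self.E_lo < self.E_hi:
            raise ValueError(
                f"synaptic thresholds must satisfy E_lo < E_hi, "
                f"got E_lo={self.E_lo}, E_hi={self.E_hi}"
            )


@dataclass
class NeuronState:
    """Instantaneous state (V, m, h) of one neuron."""

    V: float  # membrane voltage, mV
    m: float = 1.0  # sodium activation, fraction in [0, 1]
    h: float = 1.0  # sodium inactivation, fraction in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError(f"gate values must lie in [0, 1], got m={self.m}, h={self.h}")


def gating_steady_state(V, gate: GatingParams):
    """Steady-state value z_inf(V) = 1 / (1 + A exp(S (V - E_half))).

    Total function on the reals; accepts scalars or arrays.  Strictly inside
    (0, 1) whenever ``A > 0``; identically 1 when ``A = 0``.
    """
    # exp argument clipped to avoid overflow warnings far outside the
    # physiological range; the sigmoid is saturated there anyway.
    x = np.clip(gate.S * (np.asarray(V, dtype=float) - gate.E_half), -500.0, 500.0)
    out = 1.0 / (1.0 + gate.A * np.exp(x))
    return out if out.ndim else float(out)


def gating_time_constant(V, gate: GatingParams):
    """Relaxation time constant at voltage ``V``, ms.

    Constant (``gate.tau``) by default; the voltage-dependent variant is
    bell-shaped, peaking at the sigmoid midpoint and fast at both extremes.
    """
    if not gate.tau_voltage_dependent:
        out = np.full_like(np.asarray(V, dtype=float), gate.tau)
        return out if out.ndim else float(out)
    x = np.clip(gate.S * (np.asarray(V, dtype=float) - gate.E_half), -500.0, 500.0)
    ax = gate.A * np.exp(x)
    out = np.maximum(gate.tau * np.sqrt(ax) / (1.0 + ax), 1e-6)
    return out if out.ndim else float(out)


def gating_derivative(z, z_inf, tau):
    """First-order relaxation rate dz/dt = (z_inf - z) / tau, in 1/ms."""
    if np.any(np.asarray(tau) <= 0):
        raise ValueError(f"gate time constant must be positive, got {tau}")
    return (z_inf - z) / tau


def synaptic_conductance(V_pre, syn: SynapseParams):
    """Graded synaptic conductance as a function of presynaptic voltage, uS.

    Zero below ``E_lo``, linear ramp up to ``g_max`` at ``E_hi``, saturated
    above; continuous and non-decreasing everywhere.
    """
    frac = (np.asarray(V_pre, dtype=float) - syn.E_lo) / (syn.E_hi - syn.E_lo)
    out = syn.g_max * np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


def membrane_derivative(
    state: NeuronState,
    params: NeuronParams,
    syn_inputs: Sequence[tuple[float, float]] = (),
    I_app: float = 0.0,
) -> float:
    """Membrane voltage rate dV/dt in mV/ms.

    Parameters
    ----------
    state : NeuronState
        Present voltage and gate values.
    params : NeuronParams
        Electrical constants of the neuron.
    syn_inputs : sequence of (conductance uS, E_syn mV)
        Already-evaluated synaptic conductances impinging on this neuron.
    I_app : float
        Applied (electrode/afferent) current, nA; positive depolarizes.
    """
    V = state.V
    I = params.G_leak * (params.E_rest - V)
    for g, E_syn in syn_inputs:
        I += g * (E_syn - V)
    I += params.G_Na * (params.E_Na - V) * state.m * state.h
    I += I_app
    return I / params.C
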