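"""Time integration of network specifications under stimulus protocols.

The default integrator is exponential Euler: with synaptic conductances and
gate targets frozen over one step, both the membrane equation and the gate
relaxations are linear ODEs that are advanced by their exact exponential
update.  This is well suited to conductance-based leaky integrators, whose
stiffest terms are the conductance-scaled membrane relaxations.  A classical
fixed-step RK4 integrator on the fully coupled system is provided for
cross-verification.

Conventions: ``dt`` is in ms; durations, stimulus times and the exported
time grid are in seconds (the natural scale of step cycles).  Stimulus edges
are aligned to the step grid by flooring the onset and ceiling the offset.
Noise is white Gaussian current per target neuron whose per-step standard
deviation scales as ``sd / sqrt(dt)`` so that its integrated effect is
step-size invariant; the seed is recorded in the trace provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import gating_steady_state
from .network import NetworkSpec

__all__ = [
    "StimulusProtocol", "NoiseSpec", "SimulationConfig", "TraceSet",
    "SimulationError", "CompiledNetwork", "initial_state", "startup_kick", "run",
]


class SimulationError(RuntimeError):
    """Numerical failure (divergence / NaN) during integration."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Constant current step injected into one neuron.

    amplitude is signed, in nA; ``t_on``/``t_off`` in seconds.
    """

    target: str
    amplitude: float
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValueError(f"stimulus must have t_on < t_off, got [{self.t_on}, {self.t_off}]")


@dataclass(frozen=True)
class NoiseSpec:
    """White Gaussian current noise on a set of neurons.

    ``sd`` is the standard deviation in nA at 1 ms sampling; per-step values
    are scaled by ``sqrt(1 ms / dt)``.
    """

    targets: tuple[str, ...]
    sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"noise sd must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.1  # ms
    duration: float = 5.0  # s
    integrator: str = "exponential_euler"  # or "rk4"
    record_gates: bool = True
    startup_transient_blank: float = 0.5  # s, excluded by analyses/plots

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.integrator not in ("exponential_euler", "rk4"):
            raise ValueError(f"unknown integrator {self.integrator!r}")


@dataclass
class TraceSet:
    """Time-aligned voltage (and optionally gate) traces for every neuron."""

    time: np.ndarray  # (n_t,), seconds
    V: np.ndarray  # (n_t, n_neurons), mV
    neurons: list[str]
    m: np.ndarray | None = None  # (n_t, n_neurons)
    h: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.V[:, self.index(name)]

    def index(self, name: str) -> int:
        try:
            return self.neurons.index(name)
        except ValueError:
            raise KeyError(f"no neuron named {name!r} in trace set") from None


# ------------------------------------------------------------ compilation

class CompiledNetwork:
    """Array-of-struct compilation of a NetworkSpec for fast stepping."""

    def __init__(self, net: NetworkSpec):
        self.spec = net
        self.names = net.neuron_names()
        self.index = {n: i for i, n in enumerate(self.names)}
        if len(self.index) != len(self.names):
            raise SimulationError("network has duplicate neuron names")
        n = len(self.names)
        self.n = n
        g = lambda attr: np.array([getattr(nr.params, attr) for nr in net.neurons], float)
        self.C, self.G_leak, self.E_rest = g("C"), g("G_leak"), g("E_rest")
        self.G_Na, self.E_Na = g("G_Na"), g("E_Na")
        mg = [nr.params.m_gate for nr in net.neurons]
        hg = [nr.params.h_gate for nr in net.neurons]
        self.mA = np.array([x.A for x in mg]); self.mS = np.array([x.S for x in mg])
        self.mE = np.array([x.E_half for x in mg]); self.mTau = np.array([x.tau for x in mg])
        self.hA = np.array([x.A for x in hg]); self.hS = np.array([x.S for x in hg])
        self.hE = np.array([x.E_half for x in hg]); self.hTau = np.array([x.tau for x in hg])
        self.mVdep = np.array([x.tau_voltage_dependent for x in mg], bool)
        self.hVdep = np.array([x.tau_voltage_dependent for x in hg], bool)
        syn = net.synapses
        self.pre = np.array([self.index[s.pre] for s in syn], int)
        self.post = np.array([self.index[s.post] for s in syn], int)
        self.g_max = np.array([s.params.g_max for s in syn], float)
        self.E_syn = np.array([s.params.E_syn for s in syn], float)
        self.E_lo = np.array([s.params.E_lo for s in syn], float)
        self.inv_range = np.array([1.0 / (s.params.E_hi - s.params.E_lo) for s in syn], float)

    # vectorized pieces -------------------------------------------------
    def z_inf(self, V: np.ndarray, A, S, E) -> np.ndarray:
        return 1.0 / (1.0 + A * np.exp(np.clip(S * (V - E), -500.0, 500.0)))

    def tau_of(self, V: np.ndarray, A, S, E, tau_max, vdep) -> np.ndarray:
        """Per-neuron gate time constants (constant unless flagged)."""
        out = tau_max.copy() if isinstance(tau_max, np.ndarray) else np.full(self.n, tau_max)
        out = np.array(out, float)
        if np.any(vdep):
            x = np.clip(S * (V - E), -500.0, 500.0)
            ax = A * np.exp(x)
            tv = np.maximum(tau_max * np.sqrt(np.maximum(ax, 0.0)) / (1.0 + ax), 1e-6)
            out = np.where(vdep, tv, out)
        return out

    def syn_conductance(self, V: np.ndarray) -> np.ndarray:
        frac = np.clip((V[self.pre] - self.E_lo) * self.inv_range, 0.0, 1.0)
        return self.g_max * frac

    def syn_totals(self, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gs = self.syn_conductance(V)
        G = np.bincount(self.post, weights=gs, minlength=self.n)
        GE = np.bincount(self.post, weights=gs * self.E_syn, minlength=self.n)
        return G, GE

    def derivatives(self, V, m, h, I_ext):
        """Coupled RHS (dV/dt, dm/dt, dh/dt) for the RK4 path.

        Overflow is tolerated here; the step loop detects the resulting
        non-finite voltages and aborts with the offending neuron.
        """
        with np.errstate(over="ignore", invalid="ignore"):
            Gs, GsE = self.syn_totals(V)
            gna = self.G_Na * m * h
            dV = (self.G_leak * (self.E_rest - V) + GsE - Gs * V
                  + gna * (self.E_Na - V) + I_ext) / self.C
            tau_m = self.tau_of(V, self.mA, self.mS, self.mE, self.mTau, self.mVdep)
            tau_h = self.tau_of(V, self.hA, self.hS, self.hE, self.hTau, self.hVdep)
            dm = (self.z_inf(V, self.mA, self.mS, self.mE) - m) / tau_m
            dh = (self.z_inf(V, self.hA, self.hS, self.hE) - h) / tau_h
        return dV, dm, dh


def initial_state(net: NetworkSpec | CompiledNetwork):
    """Rest state: every neuron at E_rest, gates at steady state for E_rest."""
    c = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    V = c.E_rest.copy()
    m = c.z_inf(V, c.mA, c.mS, c.mE)
    h = c.z_inf(V, c.hA, c.hS, c.hE)
    return V, m, h


def startup_kick(net: NetworkSpec, side: str = "left") -> StimulusProtocol:
    """The documented symmetry-breaking stimulus: 2 nA into the extensor
    rhythm-generator neuron for the first 0.5 s of the simulation."""
    targets = net.find(role="RG", side=side, polarity="extensor")
    if not targets:
        raise SimulationError(f"no {side} RG extensor neuron in network")
    return StimulusProtocol(target=targets[0], amplitude=2.0, t_on=0.0, t_off=0.5)


def _stim_table(c: CompiledNetwork, stimuli: Sequence[StimulusProtocol],
                dt_ms: float, n_steps: int):
    """Per-stimulus (neuron index, on step, off step, amplitude)."""
    rows = []
    for s in stimuli:
        if s.target not in c.index:
            raise SimulationError(f"stimulus targets unknown neuron {s.target!r}")
        k_on = math.floor(s.t_on * 1000.0 / dt_ms)
        k_off = math.ceil(s.t_off * 1000.0 / dt_ms)
        rows.append((c.index[s.target], k_on, k_off, s.amplitude))
    return rows


def run(net: NetworkSpec | CompiledNetwork,
        stimuli: Sequence[StimulusProtocol] = (),
        noise: NoiseSpec | None = None,
        config: SimulationConfig = SimulationConfig(),
        extra_current: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
        state0: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None) -> TraceSet:
    """Integrate the network under the given protocol and return all traces.

    ``extra_current(step, I, V)`` is an optional in-place hook adding
    currents (nA) given the voltages at the start of the step; closed-loop
    runs use it.  It must be deterministic for reproducibility.
    Deterministic: identical (network, stimuli, noise seed, config) give a
    bit-identical TraceSet.
    """
    c = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    dt = config.dt
    n_steps = int(round(config.duration * 1000.0 / dt))
    stim_rows = _stim_table(c, stimuli, dt, n_steps)
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    noise_idx = None
    if noise is not None and noise.sd > 0:
        noise_idx = np.array([c.index[t] for t in noise.targets], int)
        noise_scale = noise.sd * math.sqrt(1.0 / dt)

    V, m, h = (x.copy() for x in (state0 if state0 is not None else initial_state(c)))
    nt = n_steps + 1
    Vs = np.empty((nt, c.n)); Vs[0] = V
    ms = hs = None
    if config.record_gates:
        ms = np.empty((nt, c.n)); hs = np.empty((nt, c.n))
        ms[0], hs[0] = m, h

    any_vdep = bool(np.any(c.mVdep) or np.any(c.hVdep))
    alpha_m = np.exp(-dt / c.mTau)
    alpha_h = np.exp(-dt / c.hTau)
    use_rk4 = config.integrator == "rk4"

    I_ext = np.zeros(c.n)
    for k in range(n_steps):
        I_ext[:] = 0.0
        for idx, k_on, k_off, amp in stim_rows:
            if k_on <= k < k_off:
                I_ext[idx] += amp
        if noise_idx is not None:
            I_ext[noise_idx] += noise_scale * rng.standard_normal(noise_idx.size)
        if extra_current is not None:
            extra_current(k, I_ext, V)

        if use_rk4:
            dV1, dm1, dh1 = c.derivatives(V, m, h, I_ext)
            dV2, dm2, dh2 = c.derivatives(V + 0.5 * dt * dV1, m + 0.5 * dt * dm1,
                                          h + 0.5 * dt * dh1, I_ext)
            dV3, dm3, dh3 = c.derivatives(V + 0.5 * dt * dV2, m + 0.5 * dt * dm2,
                                          h + 0.5 * dt * dh2, I_ext)
            dV4, dm4, dh4 = c.derivatives(V + dt * dV3, m + dt * dm3, h + dt * dh3, I_ext)
            V = V + dt / 6.0 * (dV1 + 2 * dV2 + 2 * dV3 + dV4)
            m = m + dt / 6.0 * (dm1 + 2 * dm2 + 2 * dm3 + dm4)
            h = h + dt / 6.0 * (dh1 + 2 * dh2 + 2 * dh3 + dh4)
            m = _clamp_gates(m, c, k, dt, "m")
            h = _clamp_gates(h, c, k, dt, "h")
        else:
            # exponential Euler: gates relax exactly toward their frozen
            # targets, then the membrane relaxes exactly toward the frozen
            # conductance equilibrium.
            m_inf = c.z_inf(V, c.mA, c.mS, c.mE)
            h_inf = c.z_inf(V, c.hA, c.hS, c.hE)
            if any_vdep:
                alpha_m = np.exp(-dt / c.tau_of(V, c.mA, c.mS, c.mE, c.mTau, c.mVdep))
                alpha_h = np.exp(-dt / c.tau_of(V, c.hA, c.hS, c.hE, c.hTau, c.hVdep))
            m = m_inf + (m - m_inf) * alpha_m
            h = h_inf + (h - h_inf) * alpha_h
            Gs, GsE = c.syn_totals(V)
            gna = c.G_Na * m * h
            G_tot = c.G_leak + Gs + gna
            V_inf = (c.G_leak * c.E_rest + GsE + gna * c.E_Na + I_ext) / G_tot
            V = V_inf + (V - V_inf) * np.exp(-dt * G_tot / c.C)

        if not np.all(np.isfinite(V)):
            bad = int(np.argmax(~np.isfinite(V)))
            raise SimulationError(
                f"integration diverged at t={(k + 1) * dt / 1000.0:.4f} s "
                f"on neuron {c.names[bad]!r}")
        Vs[k + 1] = V
        if ms is not None:
            ms[k + 1], hs[k + 1] = m, h

    time = np.arange(nt) * (dt / 1000.0)
    prov = {
        "dt_ms": dt, "duration_s": config.duration, "integrator": config.integrator,
        "startup_transient_blank_s": config.startup_transient_blank,
        "stimuli": [{"target": s.target, "amplitude_nA": s.amplitude,
                     "t_on_s": s.t_on, "t_off_s": s.t_off} for s in stimuli],
        "noise": None if noise is None else {
            "targets": list(noise.targets), "sd_nA": noise.sd, "seed": noise.seed},
        "n_steps": n_steps,
    }
    return TraceSet(time=time, V=Vs, neurons=list(c.names), m=ms, h=hs, provenance=prov)


def _clamp_gates(z: np.ndarray, c: CompiledNetwork, k: int, dt: float, which: str) -> np.ndarray:
    """Clamp tiny numerical overshoots of the gate range; large excursions are
    integration failures and abort."""
    over = np.maximum(z - 1.0, 0.0) + np.maximum(-z, 0.0)
    if np.any(over > 1e-6):
        bad = int(np.argmax(over))
        raise SimulationError(
            f"gate {which} left [0,1] by {over[bad]:.3e} at "
            f"t={(k + 1) * dt / 1000.0:.4f} s on neuron {c.names[bad]!r}")
    return np.clip(z, 0.0, 1.0)
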