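# Methods

## Model

All cells are non-spiking leaky integrators intended as rate-proxies for
neuron populations.  The membrane equation carries a leak term, graded
synaptic conductances, an optional persistent sodium current
`G_Na · m · h · (E_Na − V)`, and an applied current `I_app` added inside the
bracket before dividing by the capacitance (standard current-clamp
convention; all protocols inject currents in nA).  Gates relax first-order
toward sigmoidal steady states; the synapse conductance is a
piecewise-linear saturating function of presynaptic voltage.  The unit
system is fixed (mV, ms, nA, µS, nF) so the equations hold without
conversion factors, and every parameter table must declare exactly those
units.

Passive cells (interneurons, motoneurons, Renshaw cells) use the same type
with `G_Na = 0`; their gate parameters are inert placeholders (`A = 0`,
`τ = 1 ms`) because the sodium term is identically zero — a gate time
constant of exactly zero is rejected as invalid everywhere.

### Gate kinetics

The gate time constant is constant by default, matching the displayed model
equations.  `GatingParams(tau_voltage_dependent=True)` selects the
field-standard persistent-sodium alternative
`τ(V) = τ_max · z_∞(V) · sqrt(A e^{S(V−E)})` — bell-shaped, fast at
depolarized voltages — which gives activity-dependent burst adaptation.
The packaged defaults do not use it (see *Limitations*), but it is a
first-class option of the dynamics and the simulator.

## Architecture

* **Rhythm generator (RG)** — four neurons: an extensor/flexor pair with
  persistent sodium, weak direct mutual excitation (0.05 µS), and crossed
  inhibition through two passive interneurons.  This is the step-cycle
  clock.
* **Pattern formation (PF)** — one half-center of the same construction per
  joint group.  The knee and ankle share a single PF group (fixed muscle
  synergy), so a limb has two PF groups.
* **Motoneurons (MN)** — extensor/flexor pools per joint with Renshaw-cell
  recurrent inhibition; six MN pools per limb.
* **RG→PF coupling** — direct excitation EXT→EXT / FLX→FLX (0.5 µS) plus
  *crossed drive* from each RG neuron onto the PF interneuron that inhibits
  the antiphase PF neuron (2.0 µS).  The crossed path is what locks the PF
  half-center to the clock when the clock is slowed below the PF's intrinsic
  period; with direct excitation alone the PF slips ahead during −2 nA
  drive.  Left and right limbs share no synapses.
* **Single-joint baseline** — the legacy one-layer circuit (half-center
  synapsing directly onto the motoneurons), kept to demonstrate that without
  the PF layer every perturbation resets step timing.

Neurons are named `SIDE_JOINT_ROLE_POLARITY` (e.g. `L_hip_PF_EXT`) so
stimuli can be targeted unambiguously from configs and the CLI.

## Parameter table and calibration

The packaged table (`src/cpgnet/data/default_params.yaml`) is the model's
operating point, calibrated once by staged numeric search so that the
deafferented RG→PF→MN chain reproduces the documented behaviors:

* baseline stride 0.492 s (target 0.5 s),
* 0.348 s under +2 nA to both RG neurons (target 0.35 s),
* 0.650 s under −2 nA (target 0.65 s),
* immediate return to 0.500 s after the drive ends.

The decisive design choices: the oscillator output synapses transmit only
above −50 mV (well above the −60 mV rest), so a recovering neuron releases
its antagonist between bursts; the inhibitory reversal is shallow (−70 mV),
keeping the suppressed neuron near its escape threshold; and the persistent
sodium inactivation is slow (τ_h = 190 ms) and steep around −51 mV, so the
inhibited neuron's h-recovery is the rate-limiting step of each half-cycle.
In that *escape-dominated* regime a few nA of tonic drive moves the escape
time strongly and in the right direction (depolarization → earlier escape →
faster rhythm).  Retuning belongs in an overlay YAML merged over the base
table (`load_parameter_table(path, overlay=...)`), not in edits to the
packaged file.

## Protocols and measurement

Step cycles are rising −60 mV crossings of the extensor PF voltage, located
by linear interpolation between bracketing samples, with a 10 ms refractory
guard; the first 0.5 s startup transient (the documented 2 nA / 0.5 s kick
into the left RG extensor) is blanked.  Epoch period tables report both the
mean and the individual periods so partial cycles at stimulus edges stay
visible.

Resetting classification compares a perturbed run against an unperturbed
reference sharing every other setting.  The reference clock period is
estimated from the whole reference train; the steady-state shift is the mean
wrapped (circular) offset of the last three post-stimulus crossings in
period fractions, so a full-cycle slip counts as zero — the "reappears at
the expected time" notion of a non-resetting deletion.  The default
tolerance separating the classes is 5% of a period, exposed as an argument;
the classification is monotone in it.  Motoneuron bursts are supra-threshold
intervals at −55 mV (the MN pools approach their −60 mV rest from above
between bursts, so the burst threshold sits slightly depolarized); a burst
deletion is an inter-onset gap exceeding 1.5× the median gap.

Two stimulus onsets are *phase-aligned* by default rather than fixed in wall
clock, because the cycle phase at a given instant is an artifact of the
calibration, while the documented effects are phase-specific: the 0.1 s PF
"memory" pulse is placed so it ends at the first reference extensor onset
after 1.0 s (late flexion — it then advances the flexor→extensor switch,
shortening the extensor period that brackets it and lengthening the
following flexor period without moving later onsets), and the −10 nA
deletion pulse starts at the first extensor onset after 2.0 s (it must
interrupt ongoing extensor activity to test anything).  The windows actually
used are recorded in each experiment's provenance, and alignment can be
disabled.

## Numerics

The default integrator is exponential Euler at dt = 0.1 ms: gates relax
exactly toward their frozen targets, then the membrane relaxes exactly
toward its frozen conductance equilibrium.  It is unconditionally stable and
exact for a passive cell under step current (the closed-form test passes at
machine precision).  A classical fixed-step RK4 on the fully coupled system
is provided for cross-verification; the two agree within 0.14 mV over 1 s of
the rhythm generator at dt = 0.01 ms.  Stimulus edges are aligned to the
grid by flooring the onset and ceiling the offset.  Gates are clamped after
each step for overshoots up to 1e−6 (RK4 stage error on the steep activation
sigmoid legitimately exceeds 1e−9); larger excursions abort with the neuron
and time, as do non-finite voltages.  Noise, when requested, is white
Gaussian current with per-step standard deviation `sd · sqrt(1 ms / dt)`
(step-size-invariant integrated effect) from a mandatory recorded seed;
identical inputs give bit-identical traces.

Stride *periods* are already converged at the default step (0.4923 s at
dt = 0.1 ms vs 0.4920 s at dt = 0.01 ms).  Pointwise *voltage* agreement
under step halving reaches the 0.1 mV level only in the refined-step regime
(dt ≤ 5 µs over 1 s horizons), because the escape transitions are sharp and
their timing converges first-order; the refinement test therefore runs at
dt = 5 µs vs 2.5 µs.  Problem sizes throughout the tests (1–6 s simulations
of 4–24 neuron networks) were chosen as the smallest that exercise several
complete cycles per condition.

## Stand-in plant

The closed-loop module is explicitly a stand-in, not a biomechanical body:
one rotational degree of freedom per PF group (hip; knee–ankle lumped),
driven by an antagonistic muscle pair whose activation is a first-order
low-pass (τ = 30 ms) of a clamped linear map of MN voltage, with torque
`gain·(act_ext − act_flx) − damping·ω − stiffness·θ` integrated
semi-implicitly.  The stiffness term is a soft joint limit / passive elastic
force; it also gives the joint a well-defined steady angle under constant
activation.  Afferents are linear with clamps: velocity-proportional
(Ia-like), position-proportional (II-like), and extensor-torque-proportional
(Ib-like) currents routed to configurable neurons; the packaged demo routes
hip position into the RG half-center and lumped extensor load into the RG
extensor.  With all gains zero the closed loop reproduces the deafferented
trace bit-exactly (adding an exact 0.0 current changes nothing).  With the
demo gains, a PF deletion is followed by a phase deviation that persists
across multiple cycles instead of vanishing within one — the direction of
the slow-recovery observation — but the module cannot and does not settle
whether such slow recovery stems from sensory feedback or from contralateral
mechanical entrainment; it only makes the comparison runnable.

## Limitations

* The packaged constant-τ gate kinetics cannot reproduce one documented
  pattern-formation behavior: a 1 s, +2 nA stimulus to the extensor PF
  neuron does **not** delete extensor-motoneuron bursts in this model — the
  PF neuron keeps emitting one burst per clock cycle because its plateau is
  h-limited (the plateau self-terminates long before 1 s) and the clock's
  crossed inhibition wins every flexion phase against a 2 nA bias.  An
  extensive search over escape, bistable-plateau, and winner-take-all PF
  regimes, motoneuron-pool smoothing, and the voltage-dependent τ_h option
  found no parameterization that produces the deletion without breaking the
  other calibrated behaviors; activity-dependent inactivation kinetics
  together with a different PF operating point appear to be required.  The
  corresponding test is kept and fails.
* The plant is not calibrated to any body; closed-loop results are
  qualitative only.  Joint-angle trajectories of an articulated hindlimb are
  out of scope.
* Fast/slow gate time constants are per-gate constants (or the single
  bell-shaped option); no temperature effects or channel noise.
* The synthetic protocols are deafferented by construction; passing tests
  show the circuit logic, not fidelity to any particular animal preparation.
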