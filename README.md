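# cpgnet — two-layer locomotor CPG simulation and rhythm analysis

`cpgnet` simulates spinal central pattern generator (CPG) circuits for
mammalian hindlimb locomotion, built from **non-spiking leaky-integrator
neurons** with a persistent sodium current and **graded synapses**, and
organized in the two-layer architecture in which a **rhythm generator** (RG)
half-center keeps step-cycle time while **pattern formation** (PF)
half-centers distribute that timing to motoneuron pools.  It is aimed at
computational neuroscientists and neurorobotics researchers who want a small,
fully inspectable model of why perturbations of the PF layer produce
*non-resetting deletions* (motor bursts vanish, then reappear on the
unperturbed clock) while perturbations of the RG layer permanently reset the
rhythm.

## The model

Each neuron obeys

```
C dV/dt = G_leak (E_rest − V) + Σᵢ G_syn,i (E_syn,i − V)
          + G_Na m h (E_Na − V) + I_app
dz/dt   = (z_∞(V) − z)/τ_z ,   z_∞ = 1 / (1 + A_z exp(S_z (V − E_z))) ,  z ∈ {m, h}
```

with graded (non-spiking) synapses whose conductance ramps linearly with the
presynaptic voltage between thresholds `E_lo` and `E_hi`.  Interneurons,
motoneurons and Renshaw cells are the same type with `G_Na = 0`.  Units are
fixed package-wide to mV / ms / nA / µS / nF.

The packaged parameter table places the RG half-center in an
*escape-dominated* regime: the inhibited neuron's persistent-sodium
de-inactivation sets the switching time, so tonic drive to both RG neurons
(a midbrain-locomotor-region-style command) modulates the stride period —
+2 nA shortens ~0.5 s strides to ~0.35 s, −2 nA lengthens them to ~0.65 s.
Step cycles are measured as rising −60 mV crossings of the extensor PF
neuron.  A full limb wires one RG to a hip PF group and one *shared
knee–ankle* PF group (a fixed muscle synergy) driving six motoneuron pools
with Renshaw recurrent inhibition.  A deliberately minimal one-DOF-per-joint
plant with clamped linear Ia/II/Ib-like afferents closes the sensorimotor
loop for qualitative demonstrations.

## Worked example

```python
import cpgnet as c

net = c.build_two_layer_chain()            # RG -> hip PF -> MN pair
stim = [c.startup_kick(net)]               # 2 nA / 0.5 s symmetry breaker
for rg in sorted(net.find(role="RG")):     # descending drive to both RG cells
    stim += [c.StimulusProtocol(rg,  2.0, 1.5, 2.5),
             c.StimulusProtocol(rg, -2.0, 3.5, 4.5)]
tr = c.run(net, stim, config=c.SimulationConfig(duration=5.5))
rep = c.detect_cycles(tr.time, tr["L_hip_PF_EXT"], t_start=0.5)
for t0, t1 in [(0.5, 1.5), (1.5, 2.5), (2.5, 3.5), (3.5, 4.5)]:
    print(t0, t1, round(c.period_in_window(rep, t0, t1), 3))
```

prints

```
0.5 1.5 0.495
1.5 2.5 0.348
2.5 3.5 0.5
3.5 4.5 0.65
```

— the baseline ~0.5 s stride, the ~0.35 s stride under +2 nA drive, the
immediate return to baseline, and the ~0.65 s stride under −2 nA.  The same
experiment is available from the shell:

```bash
cpgnet experiment drive --out out/drive      # period table, traces, plot
cpgnet experiment memory --out out/memory    # PF "memory" stimuli
cpgnet experiment deletion --layer RG --out out/del   # resetting deletion
cpgnet build limb --out limb.yaml && cpgnet validate limb.yaml
cpgnet run --network limb.yaml --duration 5 --seed 7 --out traces.csv
cpgnet analyze --trace traces.csv --neuron L_hip_PF_EXT --threshold -60
```

Perturbation experiments return a `ResetReport`: a −10 nA / 0.1 s pulse into
the hip PF extensor is classified `non-resetting` (steady phase shift ≈ 0),
while the same pulse into the RG extensor is `resetting` (shift ≈ 0.19 of a
period), and a +2 nA pulse to the legacy single-layer half-center circuit is
likewise `resetting` — the separation of timing from magnitude is exactly
what the second layer buys.

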