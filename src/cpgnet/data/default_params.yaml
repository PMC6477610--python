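# Calibrated default parameters for the two-layer locomotor CPG.
#
# Unit system (fixed package-wide): mV / ms / nA / uS / nF.
# Neuron rows are parameter *classes* resolved by the network builders;
# synapse rows are keyed "PRECLASS->POSTCLASS".
#
# The oscillator operating point places the half-centers in an
# escape-dominated regime: the inhibited neuron's persistent-sodium
# de-inactivation (h recovery, tau_h = 190 ms) sets the switching time, so
# depolarizing both rhythm-generator neurons advances escape and shortens
# the stride, and hyperpolarization delays it.  The inhibitory reversal is
# deliberately shallow (-70 mV) so the suppressed neuron stays near its
# escape threshold and tonic drive currents of a few nA modulate the period
# strongly.  With this table the deafferented chain strides at ~0.5 s,
# ~0.35 s under +2 nA drive to both rhythm-generator neurons, and ~0.65 s
# under -2 nA.  Retuning belongs in an overlay file, not here.
units:
  voltage: mV
  time: ms
  current: nA
  conductance: uS
  capacitance: nF

neurons:
  RG:            # rhythm-generator half-center neuron (persistent sodium)
    C: 5.0
    G_leak: 1.0
    E_rest: -60.0
    G_Na: 1.85
    E_Na: 50.0
    m: {A: 1.0, S: -0.2, E_half: -45.0, tau: 2.0}
    h: {A: 0.5, S: 0.3, E_half: -51.0, tau: 190.0}
  PF:            # pattern-formation half-center neuron (same dynamics)
    C: 5.0
    G_leak: 1.0
    E_rest: -60.0
    G_Na: 1.85
    E_Na: 50.0
    m: {A: 1.0, S: -0.2, E_half: -45.0, tau: 2.0}
    h: {A: 0.5, S: 0.3, E_half: -51.0, tau: 190.0}
  IN:            # passive interneuron (incl. adaptor/inhibitory relay)
    C: 5.0
    G_leak: 1.0
    E_rest: -60.0
    G_Na: 0.0
  MN:            # motoneuron (non-spiking proxy for a pool)
    C: 5.0
    G_leak: 1.0
    E_rest: -60.0
    G_Na: 0.0
  RE:            # Renshaw cell
    C: 5.0
    G_leak: 1.0
    E_rest: -60.0
    G_Na: 0.0

synapses:
  # oscillator output transmits only during genuine bursts (-50..-35 mV
  # ramp, well above the -60 mV rest), so a recovering neuron releases its
  # antagonist between bursts
  RG->RG:        # weak mutual excitation between half-center neurons
    {g_max: 0.05, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
  PF->PF:
    {g_max: 0.05, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
  RG->IN:        # half-center neuron onto its inhibitory interneuron
    {g_max: 2.0, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
  IN->RG:        # interneuron inhibition of the opposite half-center
    {g_max: 1.0, E_syn: -70.0, E_lo: -60.0, E_hi: -40.0}
  PF->IN:
    {g_max: 2.0, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
  IN->PF:
    {g_max: 1.0, E_syn: -70.0, E_lo: -60.0, E_hi: -40.0}
  RG->PF:        # direct descending drive, EXT->EXT / FLX->FLX
    {g_max: 0.5, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
  RG->PFIN:      # crossed drive through the PF interneurons; locks the PF
                 # half-center to the clock for both faster and slower strides
    {g_max: 2.0, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
  PF->MN:        # pattern formation onto motoneuron
    {g_max: 1.0, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
  MN->RE:        # recurrent collateral onto Renshaw cell
    {g_max: 0.5, E_syn: -40.0, E_lo: -60.0, E_hi: -45.0}
  RE->MN:        # Renshaw recurrent inhibition
    {g_max: 0.3, E_syn: -70.0, E_lo: -60.0, E_hi: -45.0}
  HC->MN:        # single-layer legacy circuit: half-center directly onto MN
    {g_max: 1.0, E_syn: -40.0, E_lo: -50.0, E_hi: -35.0}
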