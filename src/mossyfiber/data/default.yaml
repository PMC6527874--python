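# Default mossy-fiber pearl-chain model: a soma, ten 0.2 μm × 100 μm axonal
# cylinders and ten 4 μm en passant boutons in strict alternation.
geometry:
  n_boutons: 10
  soma_diameter: 10.0      # μm (cylinder with length = diameter)
  axon_diameter: 0.2       # μm
  axon_length: 100.0       # μm
  bouton_diameter: 4.0     # μm (cylinder with length = diameter)
  nseg_per_um: 1.0         # discretization density

passive:
  cm: 1.0                  # μF cm⁻²
  rm: 10000.0              # Ω cm²
  ri: 110.0                # Ω cm
  e_leak: -81.0            # mV (replaced by per-segment retuning at run time)

channels:
  gna_axon: 50.0           # mS cm⁻², axon and boutons
  gna_soma: 10.0           # mS cm⁻²
  gk: 36.0                 # mS cm⁻², uniform
  e_na: 50.0               # mV
  e_k: -85.0               # mV

gating:
  model: hh_shifted
  params: {}               # scheme defaults (see mossyfiber.channels)

simulation:
  dt: 0.005                # ms (5 μs)
  resting_potential: -80.0 # mV
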