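# mossyfiber

Compartmental simulation of axonal action potentials and after potentials
at hippocampal mossy fibers.

Action potentials in thin central axons are followed by an after potential
lasting tens of milliseconds that modulates excitability during repetitive
firing. Its origin is hard to pin down experimentally because separating
the **capacitive component** — charge delivered passively through the axon
cable by the upstream spike — from ionic components requires simultaneous
recordings from two sites on one axon plus spatially restricted channel
block. In a simulation those manipulations are trivial. This package
implements a "pearl chain" model of the hippocampal mossy fiber — a soma
(10 μm), ten thin axonal cylinders (0.2 μm × 100 μm) and ten giant *en
passant* boutons (4 μm) in alternation — with Hodgkin–Huxley-type Na⁺, K⁺
and leak conductances, and the in-silico experiments that dissect the
after potential into its K⁺-channel and capacitive parts.

It is written for computational neuroscientists and electrophysiologists
who want a self-contained, dependency-light reimplementation of this model
with a tested solver and measurement pipeline.

## Model

Membrane potential obeys the compartmental cable equation

```
C_i dV_i/dt = − g_Na m³h (V_i−E_Na) − g_K n⁴k (V_i−E_K) − g_L (V_i−E_L)
              − Σ_j g_ij (V_i−V_j) + I_stim,i
```

with m, h, n first-order Hodgkin–Huxley gates, k a slow multiplicative
K⁺-inactivation gate (Kv1.4-like), and g_ij the axial coupling computed
from the intracellular resistivity and segment geometry. Passive
parameters: Cm = 1 μF cm⁻², Rm = 10 kΩ cm², Ri = 110 Ω cm. Densities:
g_Na = 50 mS cm⁻² (axon, boutons) / 10 mS cm⁻² (soma), g_K = 36 mS cm⁻²
everywhere; E_Na = +50 mV, E_K = −85 mV. Discretization is 1 segment per
μm (1050 compartments); integration is implicit (backward Euler, optional
Crank–Nicolson) at dt = 5 μs, with gates advanced by the exact exponential
update. Every recorded site stores the full current decomposition,
including the capacitive current I_cap = Cm·dV/dt, with a discrete charge
balance that closes to solver roundoff. See `docs/methods.md` for
assumptions, calibration, and limitations.

## Worked example

Remove Na⁺ and K⁺ conductances from the 8th axonal cylinder onward, evoke
a spike at the soma, and measure how the passively propagated
depolarization decays with distance from the last active bouton:

```python
from mossyfiber import build_mossy_fiber_model
from mossyfiber.experiments import passive_propagation_experiment

chain = build_mossy_fiber_model()          # the default pearl chain
res = passive_propagation_experiment(chain)
print(f"lambda = {res['lambda_um']:.1f} um")
print(f"spike at last active bouton = {res['ap_amplitude_mV']:.1f} mV")
print(f"passive, one spacing out    = {res['passive_amp_100um_mV']:.1f} mV")
print(f"passive, two spacings out   = {res['passive_amp_200um_mV']:.1f} mV")
```

prints

```
lambda = 59.2 um
spike at last active bouton = 117.2 mV
passive, one spacing out    = 18.7 mV
passive, two spacings out   = 5.0 mV
```

i.e. the full spike (≈117 mV) collapses to ≈19 mV one inter-bouton
spacing (≈100 μm) into the passive region and ≈5 mV two spacings out,
decaying with a length constant of ≈59 μm — much shorter than the
steady-state length constant of the same chain (≈166 μm, from
`steady_state_lambda_experiment`), because the axon cable low-pass
filters the fast spike. That residual passive depolarization is the
capacitive component of the after potential; its late phase relaxes with
τ ≈ 6.3 ms, close to the ≈7.4 ms relaxation of small hyperpolarizing
current steps at the same bouton (`step_family_experiment`).

The same experiments are available from a shell:

```
mossyfiber fig1 --out out        # spatial decay + steady-state lambda
mossyfiber fig2 --out out        # after-potential polarity vs resting Vm
mossyfiber fig6 --out out        # step relaxation vs late after potential
```

Each subcommand writes trace CSVs, a `summary.csv` of fitted quantities,
and a machine-readable `results.json`.

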