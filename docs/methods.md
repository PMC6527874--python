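# Methods

## The model

The hippocampal mossy fiber is represented as an unbranched "pearl chain":
a soma attached to ten repeats of a thin axonal cylinder followed by a
giant *en passant* bouton. Geometry and electrical parameters:

| parameter | value | notes |
|---|---|---|
| soma | 10 μm diameter | cylinder, length = diameter |
| axonal cylinder | 0.2 μm × 100 μm | ten of them |
| bouton | 4 μm diameter | cylinder, length = diameter; ten of them |
| Cm | 1 μF cm⁻² | specific membrane capacitance |
| Rm | 10 000 Ω cm² | g_L = 0.1 mS cm⁻², τ_m = 10 ms isopotential |
| Ri | 110 Ω cm | intracellular resistivity |
| g_Na | 50 mS cm⁻² axon/boutons, 10 soma | m³h gating |
| g_K | 36 mS cm⁻² uniform | n⁴·k gating |
| E_Na / E_K | +50 / −85 mV | |
| E_L | −81 mV stored default | replaced by retuning (below) |
| discretization | 1 segment μm⁻¹ | 1050 compartments |
| dt | 5 μs | backward Euler default |

Soma and boutons carry only a diameter in the source description; both are
represented as cylinders with length equal to diameter, which preserves
the lateral membrane area exposed to the solver (the convention of the
NEURON environment for such sections). Boutons strictly alternate with
axonal cylinders ("*en passant* axon with boutons every 100 μm"), the soma
attaches to the first cylinder without a hillock taper, and both chain
ends are sealed (zero axial flux). The sealed distal end produces the
characteristic amplitude boost at the 10th bouton. The bare 0.2 μm axon
has an infinite-cable length constant √(Rm·d/4Ri) ≈ 213 μm and an
isopotential time constant Rm·Cm = 10 ms; bouton loading pulls every
measured length/time constant below these bounds.

## Gating kinetics and their calibration

The published description of this model cites bouton-recorded kinetics
(and Kv1.4 parameters for K⁺ inactivation) without printing rate
equations, so the kinetics here are pluggable: schemes register by name
and a chain selects one by id. The shipped default `hh_shifted` uses the
classic squid-axon α/β expressions with three knobs:

* `rate_scale` (default **2.5**) — common multiplier on all rates.
  Chosen so the simulated bouton spike half-width is ≈0.8 ms, in the
  range measured at mossy-fiber boutons near room temperature.
* `v_shift` (default **0**) — rigid shift of all curves. None is needed:
  the unshifted threshold (≈ −55 mV) is already physiological relative to
  the −80 mV resting potential.
* `k_shift` (default **−20 mV**) — extra depolarizing shift of the K⁺
  activation gate alone. Squid n-gates are ≈18 % open at −80 mV, which
  would add a spurious resting K⁺ conductance; mossy-fiber K⁺ channels
  (Kv1 family) activate positive to about −50 mV and are closed at rest.
  With the shift, the resting K⁺ open fraction is < 10⁻⁴ and the
  subthreshold membrane is governed by the leak alone — which is what
  makes the small-signal measurements below genuinely passive.

These three numbers were fixed once, from the spike-shape and
rest-conductance criteria above, and are not tuned per experiment. A
registry slot `engel_jonas` exists for anyone holding the original
bouton-model rate tables; all quantities that depend on the spike
waveform (the transient length constant and the passive amplitude ladder)
inherit the uncertainty of this choice, while steady-state and
small-signal quantities do not.

K⁺ slow inactivation is a single first-order gate multiplied onto n⁴,
with a Boltzmann steady state (v½ = −50 mV, slope 5 mV) and a 300 ms time
constant; over single-spike protocols it stays ≈1 and matters only for
long depolarizations. It can be disabled (`use_k_inact=False`) to recover
a pure n⁴ current.

## Resting potential

Every protocol realizes its requested resting potential by retuning the
leak reversal so that the all-channels steady state equals it — the same
manipulation the original study used to move rest to −90/−100 mV. Tuning
is per segment (the soma's different Na⁺ density would otherwise leave a
sub-mV gradient), making the uniform resting profile an exact equilibrium
of the coupled system. Tuning is applied to the *base* chain before any
regional modifier, so every member of a sweep (knockout, E_K override, Cm
change) shares identical passive parameters with its control; the solver
then starts from the true steady state of the modified chain, found by a
damped Newton iteration with a banded Jacobian.

## Numerical scheme

Voltage advances by an implicit θ-scheme on the tridiagonal compartment
matrix (backward Euler θ=1 by default; Crank–Nicolson θ=½ available — at
dt = 5 μs the two agree to well under all measurement tolerances, with
spike-peak values matching to ≈0.1 mV under dt-halving). Gates advance in
a staggered operator-split substep using the exact exponential solution
of the gate ODE at the pre-step voltage, which keeps every gate in [0, 1]
unconditionally. Recorded currents are defined at the scheme's
collocation point, so the discrete charge balance

    I_cap + I_Na + I_K + I_leak + I_axial − I_stim = 0

closes to linear-solver roundoff (≲10⁻¹² of the peak current) at every
recorded instant — the recorded capacitive current is exactly the
residual of the ionic, axial and stimulus currents. A non-finite voltage
aborts the run naming the segment and time. The pipeline contains no
randomness; identical inputs reproduce identical traces bitwise.

## Measurements

* **Amplitudes** are peak Vm minus the mean over a pre-stimulus baseline
  window (0–9.5 ms; stimuli start at 10 ms).
* **Spatial decay** is a nonlinear least-squares fit of A·exp(−x/λ),
  seeded log-linearly, over sites distal to the last active bouton
  (distance measured from its distal face) or over the ten boutons
  (steady-state case). Non-decaying profiles are flagged, not fitted.
* **Temporal decay** fits V∞ + A·exp(−t/τ) with a free asymptote. Both
  the hyperpolarizing-step relaxation and the late after-potential phase
  are fitted over the same window — 5 to 40 ms after the disturbance
  (step onset, respectively spike peak) — because the first ~5 ms contain
  fast multi-exponential cable equilibration rather than the slow
  discharge under comparison. The fitted τ depends on this choice (the
  relaxation is a mode mixture, from ≈4.7 ms for early-heavy windows to
  ≈8.7 ms for the pure tail), so the experiment driver reports the fit
  for shifted windows alongside the headline value; the spread is ≈±5 %.
* **Early after-potential phase** is the mean deviation from baseline 2–5
  ms after the spike peak (within the initial 5 ms of the after
  potential, past the repolarization flank); its sign defines the
  polarity.
* **Component decomposition** baseline-aligns the control, gK-removed and
  gNa+gK-removed bouton traces and forms V_mK = control − noK, V_mNa =
  noK − noNaK, V_cap = noNaK; the sum identity holds by construction and
  the residual is reported.
* **Onset latency** between capacitive and Na⁺ currents uses the first
  crossing of 5 % of each trace's peak magnitude (linearly interpolated);
  the threshold is configurable.

## What the simulations show — and what they do not

The "data" of this package are its own simulation traces; there is no
synthetic-noise generator. Passing tests therefore demonstrate the
internal consistency of the model — that a passive capacitive wave with
the observed length/time constants survives distal channel deletion, that
the early after-potential phase follows E_K while the capacitive
component ignores it, and that the late phase matches the passive step
response — not that real mossy fibers are quantitatively captured.
Conductances deliberately absent from the model (resurgent/persistent
Na⁺, Ih, T-type Ca²⁺, extracellular K⁺ accumulation, autoreceptors) are
exactly the mechanisms proposed to explain why experimental after
potentials are depolarizing even at −80 mV, where this model predicts a
hyperpolarizing one. Branched morphology, filopodia and myelination are
out of scope.

## Problem sizes

The default model has 1050 compartments. The shipped experiments use
40–60 ms simulations at dt = 5 μs (8 000–12 000 implicit steps) for
spike protocols, 520 ms for the steady-state length constant, and a
110 ms × 8-member family for the current steps; each runs in seconds to
tens of seconds on one CPU, and the full quantitative reproduction
(`scripts/acceptance.py`) completes in about two minutes.
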