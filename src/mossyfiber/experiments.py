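"""Figure-level experiment drivers: run a protocol, measure, summarize.

Each driver returns a plain dict of fitted quantities plus the underlying
traces, so the command-line interface, the test suite, and downstream
scripts all share one measurement path.

Windows used throughout (all configurable per call):

* baseline — the pre-stimulus interval, ending 0.5 ms before stimulus onset;
* early after-potential phase — 2–5 ms after the spike peak (the initial
  5 ms of the after potential, avoiding the repolarization flank);
* late after-potential phase — 5–40 ms after the spike peak.
"""

from __future__ import annotations

import numpy as np

from .analysis import (
    ComponentTraces,
    decompose_components,
    fit_spatial_decay,
    fit_temporal_decay,
    measure_ap_amplitude,
    onset_delay,
)
from .geometry import CompartmentChain, build_mossy_fiber_model, infinite_cable_lambda
from .protocols import (
    ProtocolSpec,
    StimulusEvent,
    protocol_Cm_sweep,
    protocol_EK10_sweep,
    protocol_component_decomposition,
    protocol_passive_propagation,
    protocol_steady_state_lambda,
    protocol_step_family,
    protocol_voltage_dependency,
    run_protocol,
)

__all__ = [
    "passive_propagation_experiment",
    "steady_state_lambda_experiment",
    "voltage_dependency_experiment",
    "decomposition_experiment",
    "ek10_sweep_experiment",
    "step_family_experiment",
    "cm_sweep_experiment",
    "icap_onset_experiment",
]

STIM_ONSET = 10.0
BASELINE = (0.0, STIM_ONSET - 0.5)


def _base_chain(chain: CompartmentChain | None) -> CompartmentChain:
    return chain if chain is not None else build_mossy_fiber_model()


def _peak_time(time, vm) -> float:
    return float(time[int(np.argmax(vm))])


def _baseline_of(time, vm, window=BASELINE) -> float:
    mask = (time >= window[0]) & (time <= window[1])
    return float(np.mean(vm[mask]))


def passive_propagation_experiment(
    chain: CompartmentChain | None = None,
    knockout_start: str = "axon8",
    spacing_um: float = 10.0,
    dt: float = 0.005,
) -> dict:
    """Spatial decay of the passively propagated spike (distal knockout).

    Fits A·exp(−x/λ) to peak depolarization versus distance, with x
    measured from the distal end of the 7th bouton — the last compartment
    expressing normal Na⁺ and K⁺ conductances.  Also reports the spike
    amplitude at that last active bouton and the passive amplitudes one and
    two inter-bouton spacings into the knockout region.
    """
    ch = _base_chain(chain)
    spec = protocol_passive_propagation(
        knockout_start=knockout_start, spacing_um=spacing_um
    )
    if dt != spec.dt:
        from dataclasses import replace

        spec = replace(spec, dt=dt)
    result = run_protocol(spec, ch)
    ts = result["run"]

    x0 = ch.section_end("bouton7")
    distances, amplitudes = [], []
    for site in ts.sites:
        pos = ch.site_position(site)
        if pos <= x0 + 1e-9:
            continue
        amp = measure_ap_amplitude(ts.time, ts.vm(site), BASELINE)
        distances.append(pos - x0)
        amplitudes.append(amp)
    distances = np.asarray(distances)
    amplitudes = np.asarray(amplitudes)
    order = np.argsort(distances)
    distances, amplitudes = distances[order], amplitudes[order]

    fit = fit_spatial_decay(distances, amplitudes)
    amp = {
        f"bouton{k}": measure_ap_amplitude(ts.time, ts.vm(f"bouton{k}"), BASELINE)
        for k in range(1, 11)
    }
    return {
        "fit": fit,
        "lambda_um": fit.decay_constant,
        "distances_um": distances,
        "amplitudes_mV": amplitudes,
        "bouton_amplitudes_mV": amp,
        "ap_amplitude_mV": amp["bouton7"],
        "passive_amp_100um_mV": amp["bouton8"],
        "passive_amp_200um_mV": amp["bouton9"],
        "traces": result,
    }


def steady_state_lambda_experiment(
    chain: CompartmentChain | None = None,
) -> dict:
    """Steady-state length constant from a long weak pulse at bouton 10.

    The steady-state deflection magnitude at each bouton is fitted as a
    single exponential of distance from the injection site; the analytic
    infinite-cable λ of the bare axon is reported as the upper bound that
    bouton loading pulls the measured value below.
    """
    ch = _base_chain(chain)
    spec = protocol_steady_state_lambda()
    result = run_protocol(spec, ch)
    ts = result["run"]
    onset = spec.stimuli[0].onset
    t_end = onset + spec.meta["pulse_ms"]
    ss_window = (t_end - 50.0, t_end)

    x_inj = ch.site_position("bouton10")
    distances, deflections = [], []
    for k in range(1, 11):
        site = f"bouton{k}"
        vm = ts.vm(site)
        base = _baseline_of(ts.time, vm)
        mask = (ts.time >= ss_window[0]) & (ts.time <= ss_window[1])
        defl = abs(float(np.mean(vm[mask])) - base)
        distances.append(x_inj - ch.site_position(site))
        deflections.append(defl)
    distances = np.asarray(distances)
    deflections = np.asarray(deflections)

    fit = fit_spatial_decay(distances, deflections)
    return {
        "fit": fit,
        "lambda_um": fit.decay_constant,
        "lambda_infinite_um": infinite_cable_lambda(
            ch.passive.rm, float(ch.diameter[ch.kind == "axon"][0]), ch.passive.ri
        ),
        "distances_um": distances,
        "deflections_mV": deflections,
        "traces": result,
    }


def _afterpotential_metrics(time, vm, early=(2.0, 5.0)) -> dict:
    """Early after-potential level relative to baseline at one site."""
    base = _baseline_of(time, vm)
    t_peak = _peak_time(time, vm)
    mask = (time >= t_peak + early[0]) & (time <= t_peak + early[1])
    early_level = float(np.mean(vm[mask]) - base)
    dev = vm - base
    onset = None
    peak_dev = float(np.max(dev))
    thr = 0.1 * peak_dev
    above = np.flatnonzero(dev >= thr)
    if above.size:
        onset = float(time[int(above[0])])
    return {
        "baseline_mV": base,
        "t_peak_ms": t_peak,
        "early_afterpotential_mV": early_level,
        "polarity": "depolarizing" if early_level > 0 else "hyperpolarizing",
        "onset_ms": onset,
    }


def voltage_dependency_experiment(
    resting_potentials=(-80.0, -90.0, -100.0),
    chain: CompartmentChain | None = None,
    site: str = "bouton10",
) -> dict:
    """After-potential polarity and latency across resting potentials."""
    ch = _base_chain(chain)
    spec = protocol_voltage_dependency(resting_potentials)
    result = run_protocol(spec, ch)
    per_resting = {}
    for v in resting_potentials:
        ts = result[f"resting={v:g}"]
        per_resting[v] = _afterpotential_metrics(ts.time, ts.vm(site))
    return {"per_resting": per_resting, "traces": result, "site": site}


def decomposition_experiment(
    resting: float = -80.0,
    chain: CompartmentChain | None = None,
    site: str = "bouton10",
) -> dict:
    """Subtraction decomposition of the bouton-10 response.

    Runs control, gK-removed, and gNa+gK-removed members sharing one
    stimulus and decomposes the control deviation into V_mNa, V_mK and the
    passive capacitive component.
    """
    ch = _base_chain(chain)
    specs = protocol_component_decomposition(resting=resting)
    traces = {label: run_protocol(s, ch)["run"] for label, s in specs.items()}
    t = traces["control"].time
    comp = decompose_components(
        t,
        traces["control"].vm(site),
        traces["noK"].vm(site),
        traces["noNaK"].vm(site),
        BASELINE,
    )
    return {"components": comp, "traces": traces, "resting": resting, "site": site}


def ek10_sweep_experiment(
    values=(-65.0, -75.0, -85.0, -95.0, -105.0),
    resting: float = -80.0,
    chain: CompartmentChain | None = None,
    site: str = "bouton10",
) -> dict:
    """E_K override in the 10th axon/bouton: early phase vs E_K10.

    Runs the active sweep and the passive companion sweep (gNa and gK
    removed from the overridden region); the companion isolates the
    capacitive component and is E_K10-independent by construction.
    """
    ch = _base_chain(chain)
    active = run_protocol(protocol_EK10_sweep(values, resting=resting), ch)
    passive = run_protocol(
        protocol_EK10_sweep(values, resting=resting, passive_companion=True), ch
    )
    early = {}
    for v in values:
        ts = active[f"ek10={v:g}"]
        early[v] = _afterpotential_metrics(ts.time, ts.vm(site))["early_afterpotential_mV"]

    # spread across passive members: max pointwise voltage difference
    vms = [passive[f"ek10={v:g}"].vm(site) for v in values]
    passive_spread = float(
        max(np.max(np.abs(a - vms[0])) for a in vms[1:])
    ) if len(vms) > 1 else 0.0
    return {
        "early_afterpotential_mV": early,
        "passive_spread_mV": passive_spread,
        "active": active,
        "passive": passive,
        "site": site,
    }


def step_family_experiment(
    steps_pA=(1.0, 0.0, -1.0, -2.0, -3.0, -4.0, -5.0, -6.0),
    resting: float = -80.0,
    chain: CompartmentChain | None = None,
    late_window=(5.0, 40.0),
    step_fit_skip: float = 5.0,
    step_fit_span: float = 40.0,
) -> dict:
    """Step-relaxation τ versus after-potential late-phase τ at bouton 10.

    Both relaxations are fitted with the same window convention — from 5 ms
    to 40 ms after the disturbance (step onset, respectively spike peak) —
    so the slow phases are compared like with like; the first 5 ms are
    excluded because they contain the fast multi-exponential cable
    equilibration, not the slow discharge under comparison.  Because the
    window is a judgement call, the fit is repeated for shifted windows and
    the spread reported alongside.
    """
    ch = _base_chain(chain)
    spec = protocol_step_family(steps_pA, resting=resting)
    result = run_protocol(spec, ch)
    step_onset = spec.meta["step_onset"]

    taus = {}
    for v in steps_pA:
        if v >= 0:
            continue
        ts = result[f"step={v:g}"]
        fit = fit_temporal_decay(
            ts.time,
            ts.vm("bouton10"),
            (step_onset + step_fit_skip, step_onset + step_fit_span),
        )
        taus[v] = fit
    tau_step = float(np.mean([f.decay_constant for f in taus.values() if f.ok]))

    ts0 = result["step=0"]
    vm0 = ts0.vm("bouton10")
    t_peak = _peak_time(ts0.time, vm0)
    late_fit = fit_temporal_decay(
        ts0.time, vm0, (t_peak + late_window[0], t_peak + late_window[1])
    )
    sensitivity = {}
    for w in ((late_window[0] - 1.0, late_window[1] - 5.0),
              late_window,
              (late_window[0] + 1.0, late_window[1] + 5.0)):
        f = fit_temporal_decay(ts0.time, vm0, (t_peak + w[0], t_peak + w[1]))
        sensitivity[w] = f.decay_constant
    return {
        "tau_step_ms": tau_step,
        "step_fits": taus,
        "tau_late_ms": late_fit.decay_constant,
        "late_fit": late_fit,
        "late_window_sensitivity": sensitivity,
        "t_peak_ms": t_peak,
        "traces": result,
    }


def cm_sweep_experiment(
    values=(0.5, 1.0, 2.0),
    chain: CompartmentChain | None = None,
    site: str = "bouton8",
) -> dict:
    """Effect of specific membrane capacitance on the passive component.

    For each Cm the passive propagating transient at the first knockout
    bouton is summarized by its peak amplitude, latency to peak, and decay
    time constant.
    """
    ch = _base_chain(chain)
    spec = protocol_Cm_sweep(values)
    result = run_protocol(spec, ch)
    summary = {}
    for v in values:
        ts = result[f"cm={v:g}"]
        vm = ts.vm(site)
        base = _baseline_of(ts.time, vm)
        amp = float(np.max(vm) - base)
        t_peak = _peak_time(ts.time, vm)
        fit = fit_temporal_decay(ts.time, vm, (t_peak + 1.0, min(t_peak + 25.0, ts.time[-1])))
        summary[v] = {
            "amplitude_mV": amp,
            "t_peak_ms": t_peak,
            "decay_tau_ms": fit.decay_constant,
        }
    return {"per_cm": summary, "traces": result, "site": site}


def icap_onset_experiment(
    mode: str = "propagated",
    resting: float = -80.0,
    chain: CompartmentChain | None = None,
    site: str = "bouton10",
) -> dict:
    """Latency from capacitive- to Na⁺-current onset at the recorded bouton.

    ``mode="propagated"`` evokes the spike at the soma, so the outward
    capacitive discharge from upstream precedes the local Na⁺ current;
    ``mode="direct"`` injects a brief pulse into the recorded bouton, and
    the two onsets coincide.
    """
    ch = _base_chain(chain)
    if mode == "propagated":
        stim = StimulusEvent("soma", 0.2, STIM_ONSET, 2.0)
    elif mode == "direct":
        stim = StimulusEvent(site, 0.2, STIM_ONSET, 0.2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    spec = ProtocolSpec(
        name=f"icap_onset_{mode}",
        resting=resting,
        stimuli=(stim,),
        record_sites=("soma", site),
        duration=40.0,
        record_currents=True,
    )
    ts = run_protocol(spec, ch)["run"]
    mask = ts.time >= STIM_ONSET - 1.0
    t = ts.time[mask]
    i_cap = ts[site]["i_cap"][mask]
    i_na = ts[site]["i_na"][mask]
    i_na = i_na - float(np.mean(i_na[t < STIM_ONSET]))
    delay = onset_delay(t, i_cap, i_na)
    return {"delay_ms": delay, "traces": ts, "mode": mode, "site": site}
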