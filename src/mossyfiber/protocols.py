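"""Declarative in-silico protocols over the base mossy-fiber model.

Each figure-style experiment is encoded as a :class:`ProtocolSpec`: a base
resting potential, a set of regional modifiers (conductance knockouts, a
local E_K override, a regional Cm change), a stimulus plan, and optionally a
one-parameter sweep.  Protocols are plain data — serializable to YAML and
re-runnable from their serialized form with identical output.

Running a protocol always proceeds in the same order: the leak reversal of
the *base* chain is retuned so that the all-channels steady state equals the
requested resting potential (per segment, so the resting profile is exactly
flat); modifiers are then applied on top; finally the solver starts from the
true steady state of the modified chain.  Tuning before modification keeps
the passive parameters of every sweep member identical to the control's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .channels import get_gating_model
from .geometry import CompartmentChain, build_mossy_fiber_model
from .solver import SimulationSettings, StimulusEvent, TraceSet, integrate

__all__ = [
    "RegionModifier",
    "ProtocolSpec",
    "ProtocolResult",
    "apply_modifiers",
    "tune_resting_potential",
    "distal_sections",
    "dense_sites",
    "expand_protocol",
    "run_protocol",
    "protocol_passive_propagation",
    "protocol_steady_state_lambda",
    "protocol_voltage_dependency",
    "protocol_component_decomposition",
    "protocol_EK10_sweep",
    "protocol_step_family",
    "protocol_Cm_sweep",
]

ACTIONS = ("remove_gNa", "remove_gK", "set_EK", "set_Cm")


@dataclass(frozen=True)
class RegionModifier:
    """A modification applied to a union of whole sections.

    ``remove_gNa``/``remove_gK`` zero the channel density (geometry
    untouched); ``set_EK`` overrides the local K⁺ reversal; ``set_Cm``
    overrides the local specific capacitance.  The latter two require
    ``value``.
    """

    region: tuple
    action: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown modifier action {self.action!r}")
        if self.action in ("set_EK", "set_Cm") and self.value is None:
            raise ValueError(f"{self.action} requires a value")
        object.__setattr__(self, "region", tuple(self.region))


@dataclass(frozen=True)
class ProtocolSpec:
    """A complete, serializable experiment description."""

    name: str
    resting: float = -80.0
    modifiers: tuple = ()
    stimuli: tuple = ()
    record_sites: tuple = ("soma", "bouton10")
    duration: float = 50.0
    dt: float = 0.005
    sweep: tuple | None = None       # (parameter, (values...))
    record_currents: bool = True
    record_gates: bool = False
    record_every: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "modifiers", tuple(self.modifiers))
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        object.__setattr__(self, "record_sites", tuple(self.record_sites))
        if self.sweep is not None:
            param, values = self.sweep
            values = tuple(values)
            if not all(np.isfinite(v) for v in values):
                raise ValueError("sweep values must be finite")
            object.__setattr__(self, "sweep", (param, values))

    # ------------------------------------------------------------ serialize

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "resting": self.resting,
            "modifiers": [
                {"region": list(m.region), "action": m.action, "value": m.value}
                for m in self.modifiers
            ],
            "stimuli": [
                {"site": s.site, "amplitude": s.amplitude, "onset": s.onset,
                 "duration": s.duration}
                for s in self.stimuli
            ],
            "record_sites": list(self.record_sites),
            "duration": self.duration,
            "dt": self.dt,
            "sweep": None if self.sweep is None else [self.sweep[0], list(self.sweep[1])],
            "record_currents": self.record_currents,
            "record_gates": self.record_gates,
            "record_every": self.record_every,
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(
            name=d["name"],
            resting=d.get("resting", -80.0),
            modifiers=tuple(
                RegionModifier(tuple(m["region"]), m["action"], m.get("value"))
                for m in d.get("modifiers", [])
            ),
            stimuli=tuple(
                StimulusEvent(s["site"], s["amplitude"], s["onset"], s["duration"])
                for s in d.get("stimuli", [])
            ),
            record_sites=tuple(d.get("record_sites", ("soma", "bouton10"))),
            duration=d.get("duration", 50.0),
            dt=d.get("dt", 0.005),
            sweep=None if d.get("sweep") is None else (d["sweep"][0], tuple(d["sweep"][1])),
            record_currents=d.get("record_currents", True),
            record_gates=d.get("record_gates", False),
            record_every=d.get("record_every", 1),
            meta=d.get("meta", {}),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class ProtocolResult:
    """Traces of every member of a (possibly swept) protocol, by label."""

    spec: ProtocolSpec
    traces: dict

    def __getitem__(self, label: str) -> TraceSet:
        return self.traces[label]

    @property
    def labels(self) -> list[str]:
        return list(self.traces)


# ------------------------------------------------------------------ regions


def distal_sections(start: str, n_boutons: int = 10) -> tuple:
    """Section names from ``start`` (e.g. ``"axon8"``) to the chain end."""
    kind = "axon" if start.startswith("axon") else "bouton"
    k = int(start.removeprefix(kind))
    names = []
    if kind == "bouton":
        names.append(f"bouton{k}")
        k += 1
    for j in range(k, n_boutons + 1):
        names.append(f"axon{j}")
        names.append(f"bouton{j}")
    return tuple(names)


def dense_sites(sections, spacing_um: float = 10.0, section_lengths=None) -> tuple:
    """Evenly spaced fractional site names along the given sections.

    ``section_lengths`` maps section name → length in μm (default: 100 μm
    axons, 4 μm boutons; boutons shorter than the spacing contribute their
    center site).
    """
    sites = []
    for name in sections:
        if section_lengths and name in section_lengths:
            length = section_lengths[name]
        else:
            length = 100.0 if name.startswith("axon") else 4.0
        n_pts = max(1, int(round(length / spacing_um)))
        for j in range(n_pts):
            frac = (j + 0.5) / n_pts
            sites.append(f"{name}:{frac:.4f}")
    return tuple(sites)


def apply_modifiers(chain: CompartmentChain, modifiers) -> CompartmentChain:
    """Return a copy of the chain with regional modifiers applied.

    Modifiers compose and commute: each one touches a disjoint array, and
    knockouts are idempotent density assignments.
    """
    out = chain.copy()
    for mod in modifiers:
        mask = out.section_mask(mod.region)
        if mod.action == "remove_gNa":
            out.gna_density[mask] = 0.0
        elif mod.action == "remove_gK":
            out.gk_density[mask] = 0.0
        elif mod.action == "set_EK":
            out.e_k[mask] = mod.value
        elif mod.action == "set_Cm":
            out.cm[mask] = mod.value
    return out


def tune_resting_potential(chain: CompartmentChain, v_rest: float) -> CompartmentChain:
    """Set the leak reversal so the all-channels steady state is ``v_rest``.

    Solved per segment: with steady-state gates at v_rest, E_leak is chosen
    so the total ionic current vanishes, making the uniform profile an exact
    equilibrium of the coupled system (axial currents are then zero too).
    """
    out = chain.copy()
    model = get_gating_model(out.gating_model_id, **out.gating_params)
    ss = model.steady_state(v_rest)
    # densities in mS/cm² — the area factor cancels in the balance
    i_na = out.gna_density * float(model.open_fraction_na(ss)) * (v_rest - out.e_na)
    i_k = out.gk_density * float(model.open_fraction_k(ss)) * (v_rest - out.e_k)
    out.e_leak = v_rest + (i_na + i_k) / out.g_leak_density
    if not np.all(np.isfinite(out.e_leak)):
        raise RuntimeError("leak-reversal retuning produced non-finite values")
    return out


# -------------------------------------------------------------- run machinery


def expand_protocol(spec: ProtocolSpec):
    """Yield ``(label, concrete ProtocolSpec)`` members of a sweep.

    Sweep parameters: ``resting`` (mV), ``ek10`` (local E_K override in
    axon10+bouton10, mV), ``step`` (standing current step at bouton10, pA),
    ``cm`` (global specific capacitance, μF cm⁻²).  A spec without a sweep
    yields itself under the label ``"run"``.
    """
    if spec.sweep is None:
        yield "run", spec
        return
    param, values = spec.sweep
    for v in values:
        label = f"{param}={v:g}"
        if param == "resting":
            member = replace(spec, resting=float(v), sweep=None)
        elif param == "ek10":
            member = replace(
                spec,
                modifiers=spec.modifiers
                + (RegionModifier(("axon10", "bouton10"), "set_EK", float(v)),),
                sweep=None,
            )
        elif param == "step":
            onset = float(spec.meta.get("step_onset", 10.0))
            member = replace(
                spec,
                stimuli=spec.stimuli
                + (StimulusEvent("bouton10", float(v) * 1e-3, onset,
                                 spec.duration - onset),),
                sweep=None,
            )
        elif param == "cm":
            member = replace(
                spec,
                modifiers=spec.modifiers
                + (RegionModifier(("__all__",), "set_Cm", float(v)),),
                sweep=None,
            )
        else:
            raise ValueError(f"unknown sweep parameter {param!r}")
        yield label, member


def _prepare_chain(spec: ProtocolSpec, base: CompartmentChain) -> CompartmentChain:
    chain = tune_resting_potential(base, spec.resting)
    mods = []
    for m in spec.modifiers:
        if m.region == ("__all__",):
            m = RegionModifier(tuple(chain.section_names()), m.action, m.value)
        mods.append(m)
    return apply_modifiers(chain, mods)


def run_protocol(
    spec: ProtocolSpec,
    chain: CompartmentChain | None = None,
    method: str = "backward_euler",
) -> ProtocolResult:
    """Run a protocol (every sweep member) on a base chain.

    The default chain is the printed mossy-fiber model.  Returns traces per
    member label (``"run"`` when the protocol has no sweep).
    """
    base = chain if chain is not None else build_mossy_fiber_model()
    traces: dict[str, TraceSet] = {}
    for label, member in expand_protocol(spec):
        prepared = _prepare_chain(member, base)
        settings = SimulationSettings(
            duration=member.duration,
            dt=member.dt,
            v_init=member.resting,
            method=method,
            record_sites=member.record_sites,
            record_currents=member.record_currents,
            record_gates=member.record_gates,
            record_every=member.record_every,
        )
        ts = integrate(prepared, settings, member.stimuli)
        ts.meta["protocol"] = member.name
        ts.meta["label"] = label
        ts.meta["resting"] = member.resting
        traces[label] = ts
    return ProtocolResult(spec=spec, traces=traces)


# ---------------------------------------------------------------- protocols

SOMA_STIM = StimulusEvent("soma", 0.2, 10.0, 2.0)
ALL_BOUTONS = tuple(f"bouton{k}" for k in range(1, 11))


def protocol_passive_propagation(
    knockout_start: str = "axon8",
    stim_site: str = "soma",
    stim_amplitude: float = 0.2,
    stim_duration: float = 2.0,
    resting: float = -80.0,
    duration: float = 40.0,
    spacing_um: float = 10.0,
) -> ProtocolSpec:
    """Distal Na⁺/K⁺ knockout with a propagated somatic action potential.

    gNa and gK are removed from ``knockout_start`` (default the 8th axonal
    cylinder) through the chain end; the spike evoked at the soma (0.2 nA,
    2 ms) invades the passive region as a decaying capacitive wave.  Records
    every bouton plus densely spaced sites along the knockout region so the
    spatial decay can be fitted.
    """
    region = distal_sections(knockout_start)
    if stim_site in region or stim_site.split(":")[0] in region:
        raise ValueError("knockout region must not cover the stimulated site")
    sites = ("soma",) + ALL_BOUTONS + dense_sites(
        tuple(s for s in region if s.startswith("axon")), spacing_um
    )
    return ProtocolSpec(
        name="passive_propagation",
        resting=resting,
        modifiers=(
            RegionModifier(region, "remove_gNa"),
            RegionModifier(region, "remove_gK"),
        ),
        stimuli=(StimulusEvent(stim_site, stim_amplitude, 10.0, stim_duration),),
        record_sites=sites,
        duration=duration,
        record_currents=False,
        meta={"knockout_start": knockout_start, "stim_site": stim_site},
    )


def protocol_steady_state_lambda(
    amplitude_nA: float = -0.004,
    pulse_ms: float = 500.0,
    resting: float = -80.0,
) -> ProtocolSpec:
    """Steady-state length constant: long weak pulse into the 10th bouton.

    A 4 pA hyperpolarizing current for 500 ms; the steady-state deflection
    is read at every bouton and fitted against distance.
    """
    return ProtocolSpec(
        name="steady_state_lambda",
        resting=resting,
        stimuli=(StimulusEvent("bouton10", amplitude_nA, 10.0, pulse_ms),),
        record_sites=("soma",) + ALL_BOUTONS,
        duration=pulse_ms + 20.0,
        record_currents=False,
        record_every=10,
        meta={"pulse_ms": pulse_ms, "amplitude_nA": amplitude_nA},
    )


def protocol_voltage_dependency(
    resting_potentials=(-80.0, -90.0, -100.0),
    stim_site: str = "soma",
    duration: float = 60.0,
) -> ProtocolSpec:
    """After-potential voltage dependency: rerun at several resting levels.

    The resting potential is moved by retuning the leak reversal; the same
    somatic stimulus is applied at each level and the bouton-10 after
    potential is compared with and without baseline subtraction.
    """
    for v in resting_potentials:
        if not -120.0 <= v <= -60.0:
            raise ValueError(f"resting potential {v} mV outside [-120, -60]")
    return ProtocolSpec(
        name="voltage_dependency",
        resting=resting_potentials[0],
        stimuli=(StimulusEvent(stim_site, 0.2, 10.0, 2.0),),
        record_sites=("soma", "bouton9", "bouton10"),
        duration=duration,
        sweep=("resting", tuple(resting_potentials)),
        meta={"stim_site": stim_site},
    )


def protocol_component_decomposition(resting: float = -80.0, duration: float = 60.0):
    """Three runs sharing one stimulus for the subtraction decomposition.

    Control; gK removed from axon10+bouton10; gNa and gK removed from
    axon10+bouton10.  Returns the three specs as a dict by label.
    """
    region = ("axon10", "bouton10")
    base = ProtocolSpec(
        name="component_decomposition",
        resting=resting,
        stimuli=(SOMA_STIM,),
        record_sites=("soma", "bouton9", "bouton10"),
        duration=duration,
    )
    return {
        "control": base,
        "noK": replace(base, modifiers=(RegionModifier(region, "remove_gK"),)),
        "noNaK": replace(
            base,
            modifiers=(
                RegionModifier(region, "remove_gNa"),
                RegionModifier(region, "remove_gK"),
            ),
        ),
    }


def protocol_EK10_sweep(
    values=(-65.0, -75.0, -85.0, -95.0, -105.0),
    resting: float = -80.0,
    passive_companion: bool = False,
    duration: float = 60.0,
) -> ProtocolSpec:
    """Local E_K override in the 10th axon and bouton (E_K10 sweep).

    With ``passive_companion`` the same sweep is run with gNa and gK removed
    from the overridden region, isolating the capacitive component, which is
    then independent of E_K10 by construction.
    """
    mods = ()
    if passive_companion:
        region = ("axon10", "bouton10")
        mods = (
            RegionModifier(region, "remove_gNa"),
            RegionModifier(region, "remove_gK"),
        )
    return ProtocolSpec(
        name="ek10_sweep" + ("_passive" if passive_companion else ""),
        resting=resting,
        modifiers=mods,
        stimuli=(SOMA_STIM,),
        record_sites=("soma", "bouton9", "bouton10"),
        duration=duration,
        sweep=("ek10", tuple(values)),
        meta={"passive_companion": passive_companion},
    )


def protocol_step_family(
    steps_pA=(1.0, 0.0, -1.0, -2.0, -3.0, -4.0, -5.0, -6.0),
    resting: float = -80.0,
    step_onset: float = 10.0,
    ap_stim_onset: float = 60.0,
    duration: float = 110.0,
) -> ProtocolSpec:
    """Standing current steps at bouton 10 with a superimposed propagated AP.

    Steps (+1 to −6 pA by default) switch on 50 ms before the somatic
    stimulus, so the step relaxation and the after-potential late phase can
    both be fitted from the same member.
    """
    return ProtocolSpec(
        name="step_family",
        resting=resting,
        stimuli=(StimulusEvent("soma", 0.2, ap_stim_onset, 2.0),),
        record_sites=("soma", "bouton10"),
        duration=duration,
        sweep=("step", tuple(steps_pA)),
        meta={"step_onset": step_onset, "ap_stim_onset": ap_stim_onset},
    )


def protocol_Cm_sweep(
    values=(0.5, 1.0, 2.0),
    knockout_start: str = "axon8",
    resting: float = -80.0,
    duration: float = 40.0,
) -> ProtocolSpec:
    """Global Cm sweep of the passive propagating component.

    Each member repeats the distal-knockout passive propagation run with a
    different specific membrane capacitance; the Cm = 1.0 member reproduces
    the default passive run.
    """
    for v in values:
        if not v > 0:
            raise ValueError("Cm values must be positive")
    region = distal_sections(knockout_start)
    return ProtocolSpec(
        name="cm_sweep",
        resting=resting,
        modifiers=(
            RegionModifier(region, "remove_gNa"),
            RegionModifier(region, "remove_gK"),
        ),
        stimuli=(SOMA_STIM,),
        record_sites=("soma", "bouton7", "bouton8", "bouton9", "bouton10"),
        duration=duration,
        sweep=("cm", tuple(values)),
        meta={"knockout_start": knockout_start},
    )
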