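"""Hodgkin–Huxley-type gating kinetics for the mossy-fiber conductances.

Three conductances are modelled: a fast Na⁺ conductance gated by m³h, a
delayed-rectifier K⁺ conductance gated by n⁴ with an optional slow
inactivation gate multiplied on top (mossy-fiber K⁺ channels carry a
Kv1.4-like slow inactivation), and an ohmic leak.

The precise α/β rate functions of the mossy-fiber bouton conductances are
not uniquely pinned down by published parameter tables, so kinetics are
pluggable: schemes register by name and the chain selects one by id.  The
shipped default, ``hh_shifted``, is the classic squid-axon parameterization
with two calibration knobs:

* ``v_shift`` (mV) — rigid shift of every rate curve along the voltage axis
  (positive values move activation toward more negative potentials);
* ``rate_scale`` — a common multiplier on all rates (a temperature-like
  factor that narrows the spike without moving threshold).

Defaults are calibrated once so that, at the model's printed channel
densities, the axonal spike has a physiological threshold (≈ −60 mV) and
half-width (≲ 1 ms at a bouton), matching direct bouton recordings.  See
docs/methods.md for the calibration procedure.

Sign convention throughout: outward membrane current positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ChannelSpec, UM2_TO_CM2

__all__ = [
    "GatingState",
    "HodgkinHuxleyGating",
    "register_gating_model",
    "get_gating_model",
    "steady_state_gates",
    "advance_gating",
    "ionic_current",
]


@dataclass(frozen=True)
class GatingState:
    """Gating variables, each in [0, 1] (scalars or per-segment arrays).

    m, h — Na⁺ activation / inactivation; n — K⁺ activation; k_inact — slow
    K⁺ inactivation (1 = fully available).
    """

    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    k_inact: np.ndarray

    def clipped(self) -> "GatingState":
        return GatingState(*(np.clip(g, 0.0, 1.0) for g in (self.m, self.h, self.n, self.k_inact)))


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    denom = np.where(small, 1.0, np.expm1(x / y))
    return np.where(small, y * (1.0 - x / (2.0 * y)), x / denom)


class HodgkinHuxleyGating:
    """Squid-type HH rate functions with a voltage shift and rate scale.

    Parameters
    ----------
    v_shift : mV; applied as V' = V + v_shift before evaluating the classic
        rate expressions, so positive values make the channels open at more
        hyperpolarized potentials.
    rate_scale : multiplies every α and β; > 1 speeds all gating up.
    k_shift : mV; additional shift of the K⁺ activation (n) gate alone,
        applied on top of ``v_shift``.  The default −20 mV moves K⁺
        activation toward depolarized potentials so the delayed rectifier
        is essentially closed at the −80 mV resting potential, as it is at
        mossy-fiber boutons, while still engaging during the spike.
    k_inact_vhalf, k_inact_slope : mV; Boltzmann steady state of the slow
        K⁺ inactivation gate, 1/(1+exp((V−v½)/slope)).
    k_inact_tau : ms; its (voltage-independent) time constant.
    use_k_inact : multiplicative slow inactivation on/off; with it off the
        K⁺ current is a pure n⁴ current.
    """

    name = "hh_shifted"

    def __init__(
        self,
        v_shift: float = 0.0,
        rate_scale: float = 2.5,
        k_shift: float = -20.0,
        k_inact_vhalf: float = -50.0,
        k_inact_slope: float = 5.0,
        k_inact_tau: float = 300.0,
        use_k_inact: bool = True,
    ):
        self.v_shift = v_shift
        self.rate_scale = rate_scale
        self.k_shift = k_shift
        self.k_inact_vhalf = k_inact_vhalf
        self.k_inact_slope = k_inact_slope
        self.k_inact_tau = k_inact_tau
        self.use_k_inact = use_k_inact

    # ------------------------------------------------------------- raw rates

    def rates(self, v):
        """α, β (ms⁻¹) for m, h, n at membrane potential v (mV).

        Returns a dict ``{"m": (α, β), "h": (α, β), "n": (α, β)}``.
        """
        vs = np.asarray(v, dtype=float) + self.v_shift
        s = self.rate_scale
        am = s * 0.1 * _vtrap(-(vs + 40.0), 10.0)
        bm = s * 4.0 * np.exp(-(vs + 65.0) / 18.0)
        ah = s * 0.07 * np.exp(-(vs + 65.0) / 20.0)
        bh = s * 1.0 / (1.0 + np.exp(-(vs + 35.0) / 10.0))
        vk = vs + self.k_shift
        an = s * 0.01 * _vtrap(-(vk + 55.0), 10.0)
        bn = s * 0.125 * np.exp(-(vk + 65.0) / 80.0)
        return {"m": (am, bm), "h": (ah, bh), "n": (an, bn)}

    def k_inact_inf(self, v):
        return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - self.k_inact_vhalf) / self.k_inact_slope))

    # ------------------------------------------------------------ interfaces

    def steady_state(self, v) -> GatingState:
        """x∞ = α/(α+β) per gate (k_inact from its Boltzmann)."""
        r = self.rates(v)
        gates = {}
        for name, (a, b) in r.items():
            gates[name] = a / (a + b)
        k = self.k_inact_inf(v) if self.use_k_inact else np.ones_like(np.asarray(v, dtype=float))
        return GatingState(gates["m"], gates["h"], gates["n"], k)

    def advance(self, state: GatingState, v, dt: float) -> GatingState:
        """Exact exponential relaxation of each gate toward x∞(v) over dt.

        For fixed v the gate ODE dx/dt = α(1−x) − βx has the closed-form
        solution x(t+dt) = x∞ + (x − x∞)·exp(−dt/τ); using it keeps every
        gate inside [0, 1] unconditionally.
        """
        if not dt > 0:
            raise ValueError(f"dt must be positive, got {dt}")
        r = self.rates(v)
        new = {}
        for name, (a, b) in r.items():
            tau = 1.0 / (a + b)
            xinf = a * tau
            x = getattr(state, {"m": "m", "h": "h", "n": "n"}[name])
            new[name] = xinf + (x - xinf) * np.exp(-dt / tau)
        if self.use_k_inact:
            kinf = self.k_inact_inf(v)
            k = kinf + (state.k_inact - kinf) * np.exp(-dt / self.k_inact_tau)
        else:
            k = state.k_inact
        return GatingState(new["m"], new["h"], new["n"], k)

    def open_fraction_na(self, state: GatingState):
        return state.m**3 * state.h

    def open_fraction_k(self, state: GatingState):
        p = state.n**4
        if self.use_k_inact:
            p = p * state.k_inact
        return p

    def params(self) -> dict:
        return {
            "v_shift": self.v_shift,
            "rate_scale": self.rate_scale,
            "k_shift": self.k_shift,
            "k_inact_vhalf": self.k_inact_vhalf,
            "k_inact_slope": self.k_inact_slope,
            "k_inact_tau": self.k_inact_tau,
            "use_k_inact": self.use_k_inact,
        }


_REGISTRY: dict[str, type] = {}


def register_gating_model(cls) -> type:
    """Class decorator/function adding a kinetics scheme to the registry."""
    _REGISTRY[cls.name] = cls
    return cls


def get_gating_model(name: str, **params) -> HodgkinHuxleyGating:
    """Instantiate a registered kinetics scheme by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no gating model {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return cls(**params)


register_gating_model(HodgkinHuxleyGating)


@register_gating_model
class EngelJonasGating(HodgkinHuxleyGating):
    """Slot for the mossy-fiber-bouton kinetics of the source model.

    The published mossy-fiber bouton model has its own α/β tables fitted to
    nucleated-patch recordings; anyone holding those tables can subclass or
    parameterize this slot.  Until transcribed, it behaves as ``hh_shifted``
    with its calibrated defaults, so selecting it is explicit but safe.
    """

    name = "engel_jonas"


# --------------------------------------------------------- functional surface


def steady_state_gates(v, model: HodgkinHuxleyGating | None = None) -> GatingState:
    """Steady-state gating at potential v (mV)."""
    model = model or HodgkinHuxleyGating()
    return model.steady_state(v)


def advance_gating(state: GatingState, v, dt: float, model: HodgkinHuxleyGating | None = None) -> GatingState:
    """Advance gates over dt (ms) at fixed potential v."""
    model = model or HodgkinHuxleyGating()
    return model.advance(state, v, dt)


def ionic_current(
    v,
    state: GatingState,
    spec: ChannelSpec,
    area_um2,
    model: HodgkinHuxleyGating | None = None,
):
    """Membrane current (nA, outward positive) through one conductance.

    I_Na = g_Na·m³h·(V−E_Na); I_K = g_K·n⁴·k_inact·(V−E_K);
    I_leak = g_leak·(V−E_leak), with g the absolute conductance
    density·area.
    """
    model = model or HodgkinHuxleyGating()
    g_uS = spec.density * np.asarray(area_um2, dtype=float) * UM2_TO_CM2 * 1e3
    cid = spec.channel_id.lower()
    if cid == "na":
        p = model.open_fraction_na(state)
    elif cid == "k":
        p = model.open_fraction_k(state)
    elif cid == "leak":
        p = 1.0
    else:
        raise ValueError(f"unknown channel_id {spec.channel_id!r}")
    return g_uS * p * (np.asarray(v, dtype=float) - spec.reversal)
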