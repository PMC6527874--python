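"""Implicit time integration of the compartmental cable equation.

The membrane equation per compartment i,

    C_i dV_i/dt = −I_ion,i(V_i, gates) − Σ_j g_ij (V_i − V_j) + I_stim,i ,

is advanced with an implicit theta scheme on the tridiagonal compartment
system (backward Euler by default, Crank–Nicolson optional) with the gating
variables advanced in a staggered operator-split substep using the exact
exponential update at the pre-step voltage.  At dt = 5 μs — the default —
the two schemes agree to well below every measurement tolerance used here.

Every recorded site stores, besides Vm, the full current decomposition
(I_Na, I_K, I_leak, I_cap, net axial current, stimulus), defined so that the
discrete charge balance

    I_cap + I_Na + I_K + I_leak + I_axial_net − I_stim = 0

holds at every recorded instant to linear-solver roundoff.  Sign convention:
outward membrane current positive, depolarizing stimulus positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .channels import GatingState, HodgkinHuxleyGating, get_gating_model
from .geometry import CompartmentChain

__all__ = [
    "SimulationSettings",
    "StimulusEvent",
    "TraceSet",
    "integrate",
    "find_steady_state",
    "capacitive_current",
    "check_convergence",
]

CURRENT_KEYS = ("i_na", "i_k", "i_leak", "i_cap", "i_axial", "i_stim")


@dataclass(frozen=True)
class SimulationSettings:
    """Global integration settings.

    dt defaults to 0.005 ms (5 μs).  ``init`` selects the initial condition:
    ``"steady_state"`` solves the full nonlinear resting state of the chain
    (Newton on the coupled system) starting from ``v_init``; ``"uniform"``
    clamps every compartment to ``v_init`` with steady-state gates.
    """

    duration: float = 50.0       # ms
    dt: float = 0.005            # ms
    v_init: float = -80.0        # mV
    method: str = "backward_euler"   # or "crank_nicolson"
    record_sites: tuple = ("soma",)
    record_currents: bool = True
    record_gates: bool = False
    record_every: int = 1
    init: str = "steady_state"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")
        if self.method not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass(frozen=True)
class StimulusEvent:
    """Rectangular current injection at a named site.

    Positive amplitude depolarizes; negative (hyperpolarizing) amplitudes
    are allowed.  ``duration`` may extend beyond the simulation end.
    """

    site: str
    amplitude: float  # nA
    onset: float      # ms
    duration: float   # ms

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("stimulus duration must be >= 0")
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")


class TraceSet:
    """Recorded time series at named sites on a shared time grid.

    ``data[site][quantity]`` holds one ndarray per recorded quantity
    (``vm`` always; the current components and optionally the gating
    trajectories).  ``meta`` captures the fully resolved configuration.
    """

    def __init__(self, time: np.ndarray, data: dict, meta: dict | None = None):
        self.time = time
        self.data = data
        self.meta = dict(meta or {})

    @property
    def sites(self) -> list[str]:
        return list(self.data)

    def __getitem__(self, site: str) -> dict:
        return self.data[site]

    def vm(self, site: str) -> np.ndarray:
        return self.data[site]["vm"]

    def to_frame(self) -> pd.DataFrame:
        """Wide tidy frame: a time column plus one column per site/quantity."""
        cols = {"time": self.time}
        for site, qd in self.data.items():
            for q, arr in qd.items():
                cols[f"{site}/{q}"] = arr
        return pd.DataFrame(cols)

    def save_csv(self, path) -> None:
        """Write the traces as CSV with a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=2, default=str))

    def balance_residual(self, site: str) -> np.ndarray:
        """Discrete charge-balance residual at a recorded site, in nA."""
        d = self.data[site]
        return d["i_cap"] + d["i_na"] + d["i_k"] + d["i_leak"] + d["i_axial"] - d["i_stim"]


# ----------------------------------------------------------------- internals


def _gating(chain: CompartmentChain) -> HodgkinHuxleyGating:
    return get_gating_model(chain.gating_model_id, **chain.gating_params)


def _lap_apply(ga: np.ndarray, lap_diag: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Net axial current leaving each compartment, Σ_j g_ij (V_i − V_j)."""
    out = lap_diag * v
    out[:-1] -= ga * v[1:]
    out[1:] -= ga * v[:-1]
    return out


def _ionic_density_current(chain, model, v):
    """Total steady-gate ionic current per segment (nA) at potential v."""
    ss = model.steady_state(v)
    gl = chain.conductance_uS(chain.g_leak_density)
    gna = chain.conductance_uS(chain.gna_density) * model.open_fraction_na(ss)
    gk = chain.conductance_uS(chain.gk_density) * model.open_fraction_k(ss)
    return gl * (v - chain.e_leak) + gna * (v - chain.e_na) + gk * (v - chain.e_k)


def find_steady_state(
    chain: CompartmentChain,
    v_guess: float = -80.0,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Resting potential profile of the chain (all gates at steady state).

    Damped Newton iteration on the coupled nonlinear system
    I_ion(V) + L·V = 0 with a banded Jacobian; the ionic slope is obtained
    by a centered finite difference.  Returns the per-segment voltage (mV).
    """
    model = _gating(chain)
    ga = chain.g_axial
    n = chain.n
    lap_diag = np.zeros(n)
    lap_diag[:-1] += ga
    lap_diag[1:] += ga

    v = np.full(n, float(v_guess))
    dv = 1e-3
    for _ in range(max_iter):
        resid = _ionic_density_current(chain, model, v) + _lap_apply(ga, lap_diag, v)
        if np.max(np.abs(resid)) < tol:
            break
        slope = (
            _ionic_density_current(chain, model, v + dv)
            - _ionic_density_current(chain, model, v - dv)
        ) / (2 * dv)
        ab = np.zeros((3, n))
        ab[0, 1:] = -ga
        ab[2, :-1] = -ga
        ab[1, :] = slope + lap_diag
        step = solve_banded((1, 1), ab, resid, check_finite=False)
        step = np.clip(step, -30.0, 30.0)
        v = v - step
        if not np.all(np.isfinite(v)):
            raise RuntimeError("steady-state search diverged to non-finite voltage")
    else:
        raise RuntimeError(
            f"steady-state search did not converge (residual {np.max(np.abs(resid)):.3g} nA)"
        )
    return v


def integrate(
    chain: CompartmentChain,
    settings: SimulationSettings,
    stimuli: list[StimulusEvent] | tuple = (),
) -> TraceSet:
    """Simulate the chain and return recorded traces.

    The voltage system is solved implicitly on the tridiagonal compartment
    matrix each step; gates advance in a staggered substep via the exact
    exponential update.  Initial condition per ``settings.init``.
    """
    model = _gating(chain)
    dt = settings.dt
    theta = 1.0 if settings.method == "backward_euler" else 0.5
    n_steps = int(round(settings.duration / dt))

    n = chain.n
    C = chain.capacitance_nF()
    gl = chain.conductance_uS(chain.g_leak_density)
    gna_max = chain.conductance_uS(chain.gna_density)
    gk_max = chain.conductance_uS(chain.gk_density)
    ga = chain.g_axial
    lap_diag = np.zeros(n)
    lap_diag[:-1] += ga
    lap_diag[1:] += ga

    # initial condition
    if settings.init == "steady_state":
        v = find_steady_state(chain, v_guess=settings.v_init)
    elif settings.init == "uniform":
        v = np.full(n, float(settings.v_init))
    else:
        raise ValueError(f"unknown init mode {settings.init!r}")
    gates = model.steady_state(v)

    # stimuli resolved to segment indices
    stim_resolved = [(chain.seg_index(ev.site), ev) for ev in stimuli]

    # recording setup
    site_names = list(settings.record_sites)
    site_idx = np.array([chain.seg_index(s) for s in site_names], dtype=int)
    rec_steps = list(range(0, n_steps + 1, settings.record_every))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_of_step = {s: k for k, s in enumerate(rec_steps)}
    n_rec = len(rec_steps)

    quantities = ["vm"]
    if settings.record_currents:
        quantities += list(CURRENT_KEYS)
    if settings.record_gates:
        quantities += ["m", "h", "n", "k_inact"]
    buf = {q: np.zeros((n_rec, len(site_names))) for q in quantities}
    time = np.array([s * dt for s in rec_steps])

    def stim_vector(t_new: float) -> np.ndarray:
        i_stim = np.zeros(n)
        for idx, ev in stim_resolved:
            if ev.onset < t_new <= ev.onset + ev.duration + 1e-12:
                i_stim[idx] += ev.amplitude
        return i_stim

    def record(k_rec, v_new, v_old, g_na, g_k, i_stim, gates_now):
        # currents defined at the scheme's collocation point so the charge
        # balance identity holds exactly
        buf["vm"][k_rec] = v_new[site_idx]
        if settings.record_currents:
            v_c = v_new if theta == 1.0 else 0.5 * (v_new + v_old)
            buf["i_cap"][k_rec] = (C * (v_new - v_old) / dt)[site_idx]
            buf["i_na"][k_rec] = (g_na * (v_c - chain.e_na))[site_idx]
            buf["i_k"][k_rec] = (g_k * (v_c - chain.e_k))[site_idx]
            buf["i_leak"][k_rec] = (gl * (v_c - chain.e_leak))[site_idx]
            buf["i_axial"][k_rec] = _lap_apply(ga, lap_diag, v_c)[site_idx]
            buf["i_stim"][k_rec] = i_stim[site_idx]
        if settings.record_gates:
            for q, arr in (("m", gates_now.m), ("h", gates_now.h),
                           ("n", gates_now.n), ("k_inact", gates_now.k_inact)):
                buf[q][k_rec] = np.broadcast_to(np.asarray(arr, dtype=float), (n,))[site_idx]

    # t = 0 sample: quiescent currents (no discrete dV/dt yet)
    g_na0 = gna_max * model.open_fraction_na(gates)
    g_k0 = gk_max * model.open_fraction_k(gates)
    record(0, v, v, g_na0, g_k0, np.zeros(n), gates)

    ab = np.zeros((3, n))
    ab[0, 1:] = -theta * ga
    ab[2, :-1] = -theta * ga

    c_over_dt = C / dt
    for step in range(1, n_steps + 1):
        t_new = step * dt
        gates = model.advance(gates, v, dt)
        g_na = gna_max * model.open_fraction_na(gates)
        g_k = gk_max * model.open_fraction_k(gates)
        g_mem = gl + g_na + g_k
        b = gl * chain.e_leak + g_na * chain.e_na + g_k * chain.e_k
        i_stim = stim_vector(t_new)

        ab[1, :] = c_over_dt + theta * (g_mem + lap_diag)
        rhs = c_over_dt * v + b + i_stim
        if theta != 1.0:
            rhs -= (1.0 - theta) * (g_mem * v + _lap_apply(ga, lap_diag, v))
        v_new = solve_banded((1, 1), ab, rhs, check_finite=False)

        if not np.all(np.isfinite(v_new)):
            bad = int(np.flatnonzero(~np.isfinite(v_new))[0])
            raise RuntimeError(
                f"non-finite voltage at t = {t_new:.4f} ms in segment {bad} "
                f"({chain.kind[bad]} at x = {chain.x[bad]:.1f} μm)"
            )

        if step in rec_of_step:
            record(rec_of_step[step], v_new, v, g_na, g_k, i_stim, gates)
        v = v_new

    rec = {
        name: {q: buf[q][:, j].copy() for q in quantities}
        for j, name in enumerate(site_names)
    }
    meta = {
        "dt": dt,
        "duration": settings.duration,
        "method": settings.method,
        "v_init": settings.v_init,
        "init": settings.init,
        "record_sites": site_names,
        "stimuli": [vars(ev) for ev in stimuli],
        "gating_model": chain.gating_model_id,
        "gating_params": model.params(),
        "n_segments": n,
    }
    return TraceSet(time, rec, meta)


def capacitive_current(vm: np.ndarray, time: np.ndarray, cm: float, area_um2: float) -> np.ndarray:
    """Capacitive current I_cap = Cm·area·dV/dt from a voltage trace, in nA.

    Uses a centered finite difference (one-sided at the endpoints).  ``cm``
    in μF cm⁻², ``area_um2`` in μm², ``vm`` in mV on a uniform grid in ms.
    """
    vm = np.asarray(vm, dtype=float)
    time = np.asarray(time, dtype=float)
    if vm.size < 3:
        raise ValueError("capacitive_current needs at least 3 samples")
    c_nF = cm * area_um2 * 1e-8 * 1e3
    return c_nF * np.gradient(vm, time)


def check_convergence(
    chain: CompartmentChain,
    settings: SimulationSettings,
    stimuli: list[StimulusEvent] | tuple = (),
) -> dict:
    """Self-convergence report: integrate at dt and dt/2, compare voltages.

    Two discrepancy measures per recorded site, both in mV on the coarse
    time grid: the pointwise maximum (dominated by tiny spike-timing shifts
    whenever the trace contains a steep upstroke) and the difference of the
    peak voltage value (insensitive to timing, the measure relevant for
    amplitude-based quantities).
    """
    from dataclasses import replace

    coarse = integrate(chain, settings, stimuli)
    fine_settings = replace(
        settings, dt=settings.dt / 2, record_every=settings.record_every * 2
    )
    fine = integrate(chain, fine_settings, stimuli)
    per_site = {}
    n_common = min(len(coarse.time), len(fine.time))
    for site in coarse.sites:
        vc, vf = coarse.vm(site)[:n_common], fine.vm(site)[:n_common]
        per_site[site] = {
            "max_pointwise_mV": float(np.max(np.abs(vc - vf))),
            "peak_value_diff_mV": float(abs(np.max(vc) - np.max(vf))),
        }
    return {
        "dt": settings.dt,
        "max_discrepancy_mV": max(d["max_pointwise_mV"] for d in per_site.values()),
        "max_peak_discrepancy_mV": max(
            d["peak_value_diff_mV"] for d in per_site.values()
        ),
        "per_site": per_site,
    }
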