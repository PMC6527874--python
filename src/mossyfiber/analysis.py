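"""Measurements on simulated traces: amplitudes, exponential fits,
baseline alignment, component decomposition, onset latencies.

Spatial decay of a passively propagated depolarization and steady-state
voltage spread are both summarized by a single-exponential length constant
λ (the distance for a reduction to 1/e); relaxations in time by a single-
exponential time constant τ.  Fits use nonlinear least squares seeded by a
log-linear regression, and always report an RMS residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitResult",
    "ComponentTraces",
    "measure_ap_amplitude",
    "fit_spatial_decay",
    "fit_temporal_decay",
    "align_baseline",
    "decompose_components",
    "onset_delay",
]


@dataclass(frozen=True)
class FitResult:
    """Single-exponential fit summary.

    ``decay_constant`` is λ in μm for spatial fits or τ in ms for temporal
    fits; ``None`` when the data were flagged as non-decaying or the fit
    failed (see ``message``).
    """

    amplitude: float
    decay_constant: float | None
    offset: float
    rms_residual: float
    window: tuple = ()
    ok: bool = True
    message: str = ""


@dataclass(frozen=True)
class ComponentTraces:
    """Subtraction decomposition of the bouton action potential.

    ``v_na`` (V_mNa) and ``v_k`` (V_mK) are the membrane-potential
    components contributed by Na⁺- and K⁺-channel activation; ``v_cap`` is
    the residual passive (capacitive) component.  All are baseline-aligned
    deviations on the common grid, so v_cap + v_na + v_k reconstructs the
    control deviation by construction; ``reconstruction_error`` records the
    rounding-level residual of that identity.
    """

    time: np.ndarray
    v_na: np.ndarray
    v_k: np.ndarray
    v_cap: np.ndarray
    control: np.ndarray
    reconstruction_error: float


def _window_mask(time: np.ndarray, window) -> np.ndarray:
    t0, t1 = window
    mask = (time >= t0) & (time <= t1)
    if not np.any(mask):
        raise ValueError(f"window {window} selects no samples")
    return mask


def measure_ap_amplitude(time: np.ndarray, vm: np.ndarray, baseline_window) -> float:
    """Peak depolarization above the pre-stimulus baseline, in mV.

    Baseline is the mean Vm over ``baseline_window`` (ms); the measure is
    invariant to adding a constant offset to the whole trace.
    """
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    base = float(np.mean(vm[_window_mask(time, baseline_window)]))
    return float(np.max(vm) - base)


def _exp_model(x, a, lam):
    return a * np.exp(-x / lam)


def _exp_model_offset(x, a, lam, c):
    return a * np.exp(-x / lam) + c


def _loglinear_seed(x, y):
    """λ, A seed from a log-linear regression on the positive values."""
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        if slope < 0:
            return float(np.exp(intercept)), float(-1.0 / slope)
    return float(np.max(y)), float(max(np.ptp(x), 1.0))


def fit_spatial_decay(
    distances,
    amplitudes,
    with_offset: bool = False,
) -> FitResult:
    """Fit A·exp(−x/λ) to amplitude-vs-distance points; λ in μm.

    Requires at least three points with distinct distances.  Data that do
    not decay overall (positive amplitude trend) are flagged and no λ is
    reported.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a spatial decay fit")
    if np.unique(x).size != x.size:
        raise ValueError("distances must be distinct")
    order = np.argsort(x)
    x, y = x[order], y[order]

    trend = np.polyfit(x, y, 1)[0]
    if trend >= 0:
        return FitResult(
            amplitude=float(np.max(y)), decay_constant=None, offset=0.0,
            rms_residual=float("nan"), window=(float(x[0]), float(x[-1])),
            ok=False, message="amplitudes do not decay with distance",
        )

    a0, lam0 = _loglinear_seed(x, y)
    try:
        if with_offset:
            popt, _ = curve_fit(
                _exp_model_offset, x, y, p0=(a0, lam0, 0.0), maxfev=20000
            )
            a, lam, c = popt
            resid = y - _exp_model_offset(x, *popt)
        else:
            popt, _ = curve_fit(_exp_model, x, y, p0=(a0, lam0), maxfev=20000)
            a, lam = popt
            c = 0.0
            resid = y - _exp_model(x, *popt)
    except RuntimeError as err:
        return FitResult(
            amplitude=a0, decay_constant=None, offset=0.0,
            rms_residual=float("nan"), window=(float(x[0]), float(x[-1])),
            ok=False, message=f"fit did not converge: {err}",
        )
    return FitResult(
        amplitude=float(a), decay_constant=float(abs(lam)), offset=float(c),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        window=(float(x[0]), float(x[-1])),
    )


def fit_temporal_decay(
    time,
    vm,
    window,
) -> FitResult:
    """Fit V(t) = V∞ + A·exp(−(t−t₀)/τ) inside a time window; τ in ms.

    ``t₀`` is the window start.  The asymptote V∞ is free, so the fit
    applies equally to a relaxation toward baseline from above or below.
    """
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    mask = _window_mask(time, window)
    t = time[mask] - time[mask][0]
    y = vm[mask]
    if t.size < 4:
        raise ValueError("window selects fewer than 4 samples")

    vinf0 = y[-1]
    a0 = y[0] - vinf0
    dev = np.abs(y - vinf0)
    _, tau0 = _loglinear_seed(t, np.maximum(dev, np.max(dev) * 1e-6))
    tau0 = min(max(tau0, (t[-1] - t[0]) / 50), (t[-1] - t[0]) * 5)

    def model(tt, a, tau, vinf):
        return vinf + a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, tau0, vinf0), maxfev=20000)
    except RuntimeError as err:
        return FitResult(
            amplitude=float(a0), decay_constant=None, offset=float(vinf0),
            rms_residual=float(np.sqrt(np.mean((y - model(t, a0, tau0, vinf0)) ** 2))),
            window=tuple(window), ok=False, message=f"fit did not converge: {err}",
        )
    a, tau, vinf = popt
    resid = y - model(t, *popt)
    return FitResult(
        amplitude=float(a), decay_constant=float(abs(tau)), offset=float(vinf),
        rms_residual=float(np.sqrt(np.mean(resid**2))), window=tuple(window),
    )


def align_baseline(traces, time, window):
    """Shift each trace so its mean over the pre-response window is zero.

    Idempotent: aligning an already-aligned trace changes nothing.
    Returns a list of new arrays.
    """
    time = np.asarray(time, dtype=float)
    mask = _window_mask(time, window)
    out = []
    for tr in traces:
        tr = np.asarray(tr, dtype=float)
        out.append(tr - float(np.mean(tr[mask])))
    return out


def decompose_components(
    time,
    control,
    no_k,
    no_na_k,
    baseline_window,
) -> ComponentTraces:
    """Subtraction decomposition of the bouton response into components.

    V_mK = control − (gK removed); V_mNa = (gK removed) − (gNa+gK removed);
    the capacitive component is the fully passive (gNa+gK removed) trace.
    All three input traces must share one time grid and are baseline-aligned
    before subtraction, so the sum identity
    V_cap + V_mNa + V_mK = control deviation holds by construction.
    """
    time = np.asarray(time, dtype=float)
    arrs = [np.asarray(a, dtype=float) for a in (control, no_k, no_na_k)]
    if not all(a.shape == time.shape for a in arrs):
        raise ValueError("all traces must share the common time grid")
    ctrl, nk, nnk = align_baseline(arrs, time, baseline_window)
    v_k = ctrl - nk
    v_na = nk - nnk
    v_cap = nnk
    err = float(np.max(np.abs(v_cap + v_na + v_k - ctrl)))
    return ComponentTraces(
        time=time, v_na=v_na, v_k=v_k, v_cap=v_cap, control=ctrl,
        reconstruction_error=err,
    )


def _onset_time(time, trace, frac):
    """First crossing of frac·(peak magnitude), linearly interpolated."""
    x = np.abs(np.asarray(trace, dtype=float))
    peak = float(np.max(x))
    if peak <= 0:
        return None
    thr = frac * peak
    above = np.flatnonzero(x >= thr)
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(time[0])
    # linear interpolation between the bracketing samples
    t0, t1 = time[i - 1], time[i]
    x0, x1 = x[i - 1], x[i]
    return float(t0 + (thr - x0) / (x1 - x0) * (t1 - t0))


def onset_delay(time, i_cap, i_na, frac: float = 0.05) -> float:
    """Onset latency of |I_Na| relative to |I_cap|, in ms.

    Onset is the first crossing of ``frac`` of the respective peak
    magnitude (default 5%).  Positive values mean the capacitive current
    leads, as it does for a propagated action potential.
    """
    time = np.asarray(time, dtype=float)
    t_cap = _onset_time(time, i_cap, frac)
    t_na = _onset_time(time, i_na, frac)
    if t_cap is None or t_na is None:
        raise ValueError("no threshold crossing found in one of the traces")
    return t_na - t_cap
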