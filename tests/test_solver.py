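"""Solver correctness: equilibrium, analytic cable oracle, conservation,
linearity, reciprocity, determinism, capacitive current."""

import math
from dataclasses import replace

import numpy as np
import pytest

import mossyfiber as mf


def deviation(ts, site):
    v = ts.vm(site)
    return v - v[0]


class TestEquilibrium:
    def test_resting_chain_holds_rest(self, tuned_chain):
        """Tuned leak: no stimulus leaves every site at rest for 500 ms."""
        settings = mf.SimulationSettings(
            duration=500.0,
            record_sites=("soma", "bouton5", "bouton10"),
            record_currents=False,
            record_every=100,
        )
        ts = mf.integrate(tuned_chain, settings, [])
        for site in ts.sites:
            assert np.max(np.abs(ts.vm(site) + 80.0)) < 0.1


class TestAnalyticCable:
    """Passive sealed-end cable vs the closed-form eigenmode series."""

    L, D, I0 = 500.0, 1.0, 0.01  # μm, μm, nA
    X0 = 0.5                     # injection segment center

    @staticmethod
    def series_solution(x, t, L, d, i0, x0, passive, n_terms=4000):
        """u(x,t) for a current step at x0 on a sealed-sealed passive cable.

        Eigenmode expansion u = Σ_n ε_n·φ_n(x0)·(I/L)·(τ_n/c_m)·
        (1 − e^{−t/τ_n})·φ_n(x), φ_n = cos(nπx/L), ε_0 = 1, ε_n = 2;
        1/τ_n = (g_m + (nπ/L)²/r_a)/c_m.
        """
        circ = math.pi * d                        # μm
        c_m = passive.cm * circ * 1e-5            # nF/μm
        g_m = (1e3 / passive.rm) * circ * 1e-5    # μS/μm
        r_a = 4 * passive.ri * 1e4 / (math.pi * d**2) * 1e-6  # MΩ/μm
        n = np.arange(n_terms)[:, None]
        k = n * math.pi / L
        tau = c_m / (g_m + k**2 / r_a)            # ms
        eps = np.where(n == 0, 1.0, 2.0)
        coef = eps * np.cos(k * x0) * i0 * tau / (c_m * L)
        tt = np.atleast_1d(t)[None, :]
        amp = coef * (1.0 - np.exp(-tt / tau))    # (n_terms, nt)
        phi = np.cos(k * np.atleast_1d(x)[None, :])
        # sum over modes for each (x, t) pair requested jointly
        return amp, phi

    def test_step_response_matches_series(self):
        # leak reversal at the holding potential so the deviation from
        # uniform rest is exactly the series solution's u(x, t)
        passive = mf.PassiveParams(e_leak=-80.0)
        cable = mf.build_single_cable(self.L, self.D, passive)
        sites = ("cable:0.2", "cable:0.5")
        settings = mf.SimulationSettings(
            duration=60.0, record_sites=sites, record_currents=False,
            init="uniform",
        )
        ts = mf.integrate(
            cable, settings, [mf.StimulusEvent("cable:0.0", self.I0, 0.0, 60.0)]
        )
        xs = np.array([cable.x[cable.seg_index(s)] for s in sites])
        t_checks = np.array([2.0, 10.0, 50.0])
        amp, phi = self.series_solution(
            xs, t_checks, self.L, self.D, self.I0, self.X0, passive
        )
        for j, site in enumerate(sites):
            dev = deviation(ts, site)
            for m, t in enumerate(t_checks):
                idx = int(np.argmin(np.abs(ts.time - t)))
                analytic = float(np.sum(amp[:, m] * phi[:, j]))
                assert dev[idx] == pytest.approx(analytic, rel=0.01), (site, t)


class TestChargeConservation:
    def test_balance_identity_at_every_bouton(self, control_prop):
        """I_cap + I_Na + I_K + I_leak + I_axial − I_stim = 0 per step."""
        for site in control_prop.sites:
            d = control_prop[site]
            peak = max(np.max(np.abs(d[k])) for k in
                       ("i_na", "i_k", "i_cap", "i_axial"))
            resid = np.abs(control_prop.balance_residual(site)[1:])
            assert resid.max() <= 1e-6 * peak

    def test_balance_identity_crank_nicolson(self, tuned_chain):
        settings = mf.SimulationSettings(
            duration=15.0, method="crank_nicolson",
            record_sites=("soma", "bouton3"),
        )
        ts = mf.integrate(tuned_chain, settings,
                          [mf.StimulusEvent("soma", 0.2, 2.0, 2.0)])
        for site in ts.sites:
            d = ts[site]
            peak = max(np.max(np.abs(d[k])) for k in ("i_na", "i_k", "i_cap"))
            assert np.abs(ts.balance_residual(site)[1:]).max() <= 1e-6 * peak


class TestPassiveLinearity:
    def test_response_scales_with_stimulus(self, passive_chain):
        settings = mf.SimulationSettings(
            duration=40.0, record_sites=("bouton8", "soma"),
            record_currents=False,
        )
        ts1 = mf.integrate(passive_chain, settings,
                           [mf.StimulusEvent("bouton5", 0.002, 5.0, 30.0)])
        ts2 = mf.integrate(passive_chain, settings,
                           [mf.StimulusEvent("bouton5", 0.004, 5.0, 30.0)])
        for site in ts1.sites:
            d1, d2 = deviation(ts1, site), deviation(ts2, site)
            # solver tolerance: the steady-state Newton residual leaves a
            # common sub-1e-6 mV drift in both runs
            assert np.allclose(2.0 * d1, d2, atol=1e-6)


class TestReciprocity:
    def test_transfer_response_symmetric(self, passive_chain):
        settings = mf.SimulationSettings(
            duration=40.0, record_sites=("soma", "bouton10"),
            record_currents=False,
        )
        stim = dict(amplitude=0.004, onset=5.0, duration=30.0)
        a = mf.integrate(passive_chain, settings,
                         [mf.StimulusEvent("soma", **stim)])
        b = mf.integrate(passive_chain, settings,
                         [mf.StimulusEvent("bouton10", **stim)])
        assert np.allclose(
            deviation(a, "bouton10"), deviation(b, "soma"), atol=1e-6
        )


class TestDeterminism:
    def test_identical_inputs_identical_traces(self, tuned_chain):
        settings = mf.SimulationSettings(duration=5.0, record_sites=("soma",))
        stim = [mf.StimulusEvent("soma", 0.2, 1.0, 2.0)]
        a = mf.integrate(tuned_chain, settings, stim)
        b = mf.integrate(tuned_chain, settings, stim)
        for q in a["soma"]:
            assert np.array_equal(a["soma"][q], b["soma"][q])


class TestCapacitiveCurrent:
    def test_constant_voltage_gives_zero(self):
        t = np.arange(0, 1.0, 0.005)
        assert np.allclose(
            mf.capacitive_current(np.full_like(t, -80.0), t, 1.0, 50.0), 0.0
        )

    def test_ramp_gives_constant(self):
        t = np.arange(0, 1.0, 0.005)
        slope = 3.0  # mV/ms
        i = mf.capacitive_current(-80.0 + slope * t, t, 1.0, 50.0)
        expected = 1.0 * 50.0 * 1e-5 * slope  # nF × mV/ms = nA
        assert np.allclose(i, expected)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mf.capacitive_current(np.array([1.0, 2.0]), np.array([0.0, 1.0]),
                                  1.0, 50.0)


class TestConvergence:
    def test_passive_self_convergence_below_hundredth_mV(self, passive_chain):
        settings = mf.SimulationSettings(
            duration=25.0, record_sites=("bouton10",), record_currents=False
        )
        report = mf.check_convergence(
            passive_chain, settings,
            [mf.StimulusEvent("bouton10", -0.006, 5.0, 20.0)]
        )
        assert report["max_discrepancy_mV"] < 0.01

    def test_spiking_peak_value_converged(self, convergence_report):
        assert convergence_report["max_peak_discrepancy_mV"] < 0.5


class TestSchemes:
    def test_backward_euler_and_crank_nicolson_agree_on_peak(self, tuned_chain):
        stim = [mf.StimulusEvent("soma", 0.2, 2.0, 2.0)]
        peaks = {}
        for method in ("backward_euler", "crank_nicolson"):
            settings = mf.SimulationSettings(
                duration=15.0, method=method, record_sites=("bouton5",),
                record_currents=False,
            )
            peaks[method] = mf.integrate(tuned_chain, settings, stim).vm("bouton5").max()
        assert peaks["backward_euler"] == pytest.approx(
            peaks["crank_nicolson"], abs=0.5
        )


class TestDiagnostics:
    def test_non_finite_voltage_aborts_with_location(self, tuned_chain):
        settings = mf.SimulationSettings(duration=1.0, record_sites=("soma",))
        with pytest.raises(RuntimeError, match="segment"):
            mf.integrate(tuned_chain, settings,
                         [mf.StimulusEvent("soma", float("nan"), 0.1, 0.5)])

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            mf.SimulationSettings(duration=1.0, dt=0.0)
        with pytest.raises(ValueError):
            mf.SimulationSettings(duration=1.0, method="leapfrog")
        with pytest.raises(ValueError):
            mf.StimulusEvent("soma", 0.1, onset=-1.0, duration=1.0)


class TestTraceSetIO:
    def test_frame_and_csv_roundtrip(self, tmp_path, tuned_chain):
        settings = mf.SimulationSettings(duration=2.0, record_sites=("soma",))
        ts = mf.integrate(tuned_chain, settings,
                          [mf.StimulusEvent("soma", 0.2, 0.5, 1.0)])
        frame = ts.to_frame()
        assert "time" in frame.columns
        assert "soma/vm" in frame.columns
        assert "soma/i_cap" in frame.columns
        path = tmp_path / "traces.csv"
        ts.save_csv(path)
        assert path.exists()
        assert path.with_suffix(".csv.meta.json").exists()
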