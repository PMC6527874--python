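"""Gating kinetics: rates, steady states, exact exponential updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import mossyfiber as mf
from mossyfiber.channels import HodgkinHuxleyGating, get_gating_model

MODEL = HodgkinHuxleyGating()
V_GRID = np.linspace(-120.0, 60.0, 181)


class TestRates:
    def test_rates_nonnegative_over_physiological_range(self):
        r = MODEL.rates(V_GRID)
        for a, b in r.values():
            assert np.all(a >= 0)
            assert np.all(b >= 0)

    def test_vtrap_singularity_is_removable(self):
        # α_m has a removable singularity; values straddling it are smooth
        v0 = -40.0 - MODEL.v_shift
        vals = MODEL.rates(np.array([v0 - 1e-9, v0, v0 + 1e-9]))["m"][0]
        assert np.ptp(vals) < 1e-6


class TestSteadyState:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(v=st.floats(-120.0, 60.0))
    def test_gates_bounded(self, v):
        ss = mf.steady_state_gates(v)
        for g in (ss.m, ss.h, ss.n, ss.k_inact):
            assert 0.0 <= float(g) <= 1.0

    def test_hyperpolarized_limits(self):
        ss = mf.steady_state_gates(-120.0)
        assert float(ss.m) < 0.01
        assert float(ss.h) > 0.95

    def test_depolarized_limits(self):
        ss = mf.steady_state_gates(40.0)
        assert float(ss.m) > 0.95
        assert float(ss.h) < 0.05

    def test_k_closed_at_rest(self):
        # mossy-fiber delayed rectifier contributes no resting conductance
        ss = mf.steady_state_gates(-80.0)
        assert float(MODEL.open_fraction_k(ss)) < 1e-4

    def test_steady_state_is_fixed_point_of_advance(self):
        for v in (-100.0, -80.0, -50.0, 0.0):
            ss = mf.steady_state_gates(v)
            adv = mf.advance_gating(ss, v, dt=5.0)
            for a, b in zip((ss.m, ss.h, ss.n, ss.k_inact),
                            (adv.m, adv.h, adv.n, adv.k_inact)):
                assert float(b) == pytest.approx(float(a), rel=1e-10)


class TestAdvance:
    def test_converges_to_steady_state(self):
        state = mf.steady_state_gates(-80.0)
        v = -20.0
        for _ in range(2000):
            state = mf.advance_gating(state, v, dt=1.0)
        target = mf.steady_state_gates(v)
        assert float(state.m) == pytest.approx(float(target.m), abs=1e-9)
        assert float(state.n) == pytest.approx(float(target.n), abs=1e-9)

    def test_small_dt_matches_forward_euler_slope(self):
        state = mf.steady_state_gates(-80.0)
        v = -30.0
        dt = 1e-7
        adv = mf.advance_gating(state, v, dt)
        r = MODEL.rates(v)
        for gate, (a, b) in r.items():
            x = float(getattr(state, gate))
            slope = float(a) * (1 - x) - float(b) * x
            numeric = (float(getattr(adv, gate)) - x) / dt
            assert numeric == pytest.approx(slope, rel=1e-4)

    def test_staircase_matches_reference_ode_integration(self):
        # piecewise-constant V: the exponential update is exact per plateau,
        # so it must agree with a tightly-tolerated ODE solve of the same
        # forcing to near machine precision
        plateaus = [(-80.0, 0.4), (-20.0, 0.3), (-60.0, 0.5), (10.0, 0.2)]
        dt = 0.01
        state = mf.steady_state_gates(plateaus[0][0])
        x0 = [float(state.m), float(state.h), float(state.n)]

        # reference: integrate each plateau with solve_ivp
        ref = np.array(x0)
        for v, dur in plateaus:
            r = MODEL.rates(v)
            rates = [(float(a), float(b)) for a, b in
                     (r["m"], r["h"], r["n"])]

            def rhs(_, x):
                return [a * (1 - xi) - b * xi for (a, b), xi in zip(rates, x)]

            sol = solve_ivp(rhs, (0.0, dur), ref, rtol=1e-11, atol=1e-13)
            ref = sol.y[:, -1]

        for v, dur in plateaus:
            for _ in range(int(round(dur / dt))):
                state = mf.advance_gating(state, v, dt)
        got = np.array([float(state.m), float(state.h), float(state.n)])
        assert np.allclose(got, ref, atol=1e-8)

    def test_rejects_non_positive_dt(self):
        state = mf.steady_state_gates(-80.0)
        with pytest.raises(ValueError):
            mf.advance_gating(state, -80.0, dt=0.0)


class TestIonicCurrent:
    AREA = 50.0  # μm²

    def test_zero_driving_force(self):
        spec = mf.ChannelSpec("K", 36.0, -85.0)
        state = mf.steady_state_gates(0.0)  # K well open
        assert mf.ionic_current(-85.0, state, spec, self.AREA) == pytest.approx(0.0)

    def test_saturated_na_gates(self):
        spec = mf.ChannelSpec("Na", 50.0, 50.0)
        state = mf.GatingState(m=1.0, h=1.0, n=0.0, k_inact=1.0)
        got = mf.ionic_current(0.0, state, spec, self.AREA)
        expected = -50.0 * self.AREA * 1e-5 * 50.0  # g_uS × (0 − E_Na), inward
        assert got == pytest.approx(expected)
        assert got < 0

    def test_tuned_rest_balances_to_zero(self):
        # with the leak reversal retuned, the summed ionic current at the
        # resting potential vanishes for every segment
        from mossyfiber.protocols import tune_resting_potential
        from mossyfiber.solver import _ionic_density_current

        ch = tune_resting_potential(mf.build_mossy_fiber_model(), -80.0)
        model = get_gating_model(ch.gating_model_id, **ch.gating_params)
        i = _ionic_density_current(ch, model, np.full(ch.n, -80.0))
        assert np.max(np.abs(i)) < 1e-12

    def test_unknown_channel_rejected(self):
        state = mf.steady_state_gates(-80.0)
        with pytest.raises(ValueError):
            mf.ionic_current(-80.0, state, mf.ChannelSpec("Ca", 1.0, 120.0), 1.0)


class TestKInactivation:
    def test_multiplicative_switch(self):
        # with inactivation off, the K current is a pure n⁴ current:
        # the open fractions agree whenever k_inact = 1
        on = HodgkinHuxleyGating(use_k_inact=True)
        off = HodgkinHuxleyGating(use_k_inact=False)
        state = mf.GatingState(m=0.2, h=0.6, n=0.7, k_inact=1.0)
        assert float(on.open_fraction_k(state)) == pytest.approx(
            float(off.open_fraction_k(state))
        )
        half = mf.GatingState(m=0.2, h=0.6, n=0.7, k_inact=0.5)
        assert float(on.open_fraction_k(half)) == pytest.approx(
            0.5 * float(off.open_fraction_k(half))
        )

    def test_slow_timescale(self):
        # the inactivation gate barely moves over a single-spike timescale
        state = mf.steady_state_gates(-80.0)
        adv = mf.advance_gating(state, 0.0, dt=2.0)
        assert abs(float(adv.k_inact) - float(state.k_inact)) < 0.01


class TestRegistry:
    def test_lookup_by_name(self):
        assert isinstance(get_gating_model("hh_shifted"), HodgkinHuxleyGating)
        assert get_gating_model("engel_jonas").name == "engel_jonas"

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            get_gating_model("nonexistent_scheme")

    def test_params_roundtrip(self):
        m = HodgkinHuxleyGating(rate_scale=3.5)
        again = get_gating_model("hh_shifted", **m.params())
        assert again.rate_scale == 3.5
        assert again.k_shift == m.k_shift
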