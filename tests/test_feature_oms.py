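"""OMS divider, skewed buffer, field pipeline and RC transient."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import retinasim as rs
from retinasim.core import BipolarMap
from retinasim.feature_oms import AnalogParams, oms_pipeline, oms_spike, oms_transient, oms_vint

P = AnalogParams()  # vdd 0.8, g0 1, trip at 0.55 vdd


class TestVint:
    def test_keeper_only_rests_at_mid_rail(self):
        assert oms_vint(0, 0, P) == pytest.approx(P.vdd / 2)

    def test_divider_example(self):
        # eight center activations, no surround: (6.4 + 0.4) / 9
        assert oms_vint(8, 0, P, w_c=1.0, w_s=1.0) == pytest.approx(6.8 / 9)

    def test_balance_identity(self):
        # equal pull-up and pull-down strengths pin the node at vdd/2
        assert oms_vint(6, 8, P, w_c=4.0, w_s=3.0) == pytest.approx(P.vdd / 2)

    @given(
        n_c=st.integers(0, 200),
        n_s=st.integers(0, 500),
        w=st.floats(0.1, 4.0),
        g0=st.floats(0.1, 10.0),
    )
    def test_bounds_strictly_inside_rails(self, n_c, n_s, w, g0):
        p = AnalogParams(g0=g0)
        v = float(oms_vint(n_c, n_s, p, w_c=w, w_s=w / 2))
        assert 0.0 < v < p.vdd

    @given(n_c=st.integers(0, 50), n_s=st.integers(0, 50))
    def test_strict_monotonicity(self, n_c, n_s):
        v = float(oms_vint(n_c, n_s, P, w_c=1.0, w_s=0.5))
        assert float(oms_vint(n_c + 1, n_s, P, w_c=1.0, w_s=0.5)) > v
        assert float(oms_vint(n_c, n_s + 1, P, w_c=1.0, w_s=0.5)) < v


class TestSpike:
    def test_quiescent_node_silent(self):
        assert not oms_spike(P.vdd / 2, P)

    def test_trip_point_is_strict(self):
        assert not oms_spike(P.v_th_oms, P)
        assert oms_spike(np.nextafter(P.v_th_oms, 1.0), P)

    def test_divider_example_spikes_at_low_trip(self):
        p = AnalogParams(v_th_oms=0.44)
        assert oms_spike(6.8 / 9, p)


class TestPipeline:
    def test_no_bipolar_no_spikes(self, rf63):
        bip = BipolarMap(np.zeros((3, 63, 63), dtype=np.int8))
        out = oms_pipeline(bip, rf63, P)
        assert (out.side == "none").all()
        assert np.allclose(out.v_int, P.vdd / 2)

    def test_half_center_activation_spikes_only_that_field(self, rf63):
        # fill 50 % of one field's center with signals and nothing else
        f = (1, 1)
        data = np.zeros((1, 63 * 63), dtype=np.int8)
        half = rf63.centers[f][: rf63.centers[f].size // 2]
        data[0, half] = 1
        out = oms_pipeline(BipolarMap(data.reshape(1, 63, 63)), rf63, P)
        spiking = out[out.side == "high"]
        assert set(zip(spiking.field_row, spiking.field_col)) == {f}

    def test_on_and_off_signals_both_count(self, rf63):
        f = (1, 1)
        idx = rf63.centers[f][:40]
        on = np.zeros((1, 63 * 63), dtype=np.int8)
        on[0, idx] = 1
        off = np.zeros_like(on)
        off[0, idx] = -1
        v_on = oms_pipeline(BipolarMap(on.reshape(1, 63, 63)), rf63, P)
        v_off = oms_pipeline(BipolarMap(off.reshape(1, 63, 63)), rf63, P)
        assert np.allclose(v_on.v_int, v_off.v_int)

    def test_geometry_mismatch_rejected(self, rf63):
        bip = BipolarMap(np.zeros((2, 10, 10), dtype=np.int8))
        with pytest.raises(ValueError, match="geometry"):
            oms_pipeline(bip, rf63, P)

    def test_dvs_and_ideal_paths_agree_on_global_motion(self, rf63, scene_cache):
        stack, _ = scene_cache("oms_global_only")
        ideal = rs.detect_bipolar_ideal(stack)
        events = rs.dvs_events(stack)
        out_i = oms_pipeline(ideal, rf63, P)
        out_e = oms_pipeline(events, rf63, P)
        assert (out_i.side == "none").all()
        assert (out_e.side == "none").all()


class TestTransient:
    def test_held_schedule_reaches_steady_state(self):
        p = AnalogParams(c_int=2.0, tau_mode="rc")
        g_total = 1.0 * 10 + p.g0
        tau = p.c_int / g_total
        t, v = oms_transient([(12 * tau, 10, 0)], p, w_c=1.0, w_s=1.0)
        v_ss = float(oms_vint(10, 0, p, w_c=1.0, w_s=1.0))
        gap = abs(v_ss - p.vdd / 2)
        # exponential settling: residual bounded by gap * e^(-t/tau), and
        # below 0.1 mV once ~10 tau have elapsed
        res5 = np.abs(v[t >= 5 * tau] - v_ss)
        assert np.all(res5 <= gap * np.exp(-5) * 1.01)
        assert np.all(np.abs(v[t >= 10 * tau] - v_ss) < 1e-4)

    def test_zero_tau_limit_is_the_staircase(self):
        p = AnalogParams(c_int=1e-12, tau_mode="rc")
        t, v = oms_transient([(1.0, 4, 0), (1.0, 0, 8)], p, w_c=1.0, w_s=1.0)
        first = v[(t > 0.2) & (t < 0.9)]
        second = v[t > 1.2]
        assert np.allclose(first, float(oms_vint(4, 0, p, w_c=1, w_s=1)))
        assert np.allclose(second, float(oms_vint(0, 8, p, w_c=1, w_s=1)))

    def test_increasing_surround_steps_drive_node_down(self):
        # mirrors the staircase protocol: fixed center activation, surround
        # stepped up -> settled voltage decreases monotonically
        p = AnalogParams(c_int=0.5, tau_mode="rc")
        schedule = [(5.0, 10, n_s) for n_s in (0, 2, 4, 8, 16)]
        t, v = oms_transient(schedule, p, w_c=1.0, w_s=1.0)
        settled = [v[np.searchsorted(t, 5.0 * (k + 1)) - 1] for k in range(5)]
        assert np.all(np.diff(settled) < 0)

    def test_matches_numerical_ode_integration(self):
        # independent oracle: integrate dV/dt = (G_u vdd + g0 vdd/2
        # - V (G_u + G_d + g0)) / c_int with scipy and compare
        from scipy.integrate import solve_ivp

        p = AnalogParams(c_int=2.0, tau_mode="rc")
        schedule = [(3.0, 6, 1), (3.0, 2, 9)]
        t, v = oms_transient(schedule, p, samples_per_segment=200,
                             w_c=1.0, w_s=1.0)

        def rhs_for(n_c, n_s):
            def rhs(t, y):
                g_u, g_d = 1.0 * n_c, 1.0 * n_s
                return [
                    (g_u * p.vdd + p.g0 * p.vdd / 2
                     - y[0] * (g_u + g_d + p.g0)) / p.c_int
                ]
            return rhs

        y0, t0 = p.vdd / 2, 0.0
        oracle = np.empty_like(v)
        for seg, (duration, n_c, n_s) in enumerate(schedule):
            sel = slice(seg * 200, (seg + 1) * 200)
            tt = np.unique(np.clip(t[sel] - t0, 0.0, duration))
            sol = solve_ivp(rhs_for(n_c, n_s), (0.0, duration), [y0],
                            t_eval=tt, rtol=1e-9, atol=1e-12)
            oracle[sel] = np.interp(t[sel] - t0, sol.t, sol.y[0])
            y0 = sol.y[0][-1]
            t0 += duration
        assert np.allclose(v, oracle, atol=5e-5)
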