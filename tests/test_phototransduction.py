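"""Bipolar generation: APS calibration, ideal contrast rule, DVS events."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import retinasim as rs
from retinasim.core import FrameStack
from retinasim.phototransduction import (
    PixelParams,
    aps_voltage,
    detect_bipolar_aps,
    detect_bipolar_ideal,
    dvs_events,
    dvs_log_voltage,
    sampler_subtract,
    threshold_bipolar,
)

P = PixelParams()


def stack_1px(values, period=1000.0) -> FrameStack:
    return FrameStack(np.asarray(values, float).reshape(-1, 1, 1), period)


class TestApsVoltage:
    def test_zero_light_gives_reset_level(self):
        assert aps_voltage(0.0, P) == pytest.approx(P.v_reset)

    def test_two_point_calibration_solves_printed_anchors(self):
        # the mean pixel outputs at the two reference illuminances, with a
        # 30 % contrast between them, pin down (alpha * I1, v_reset) via a
        # 2x2 linear solve: V(I1) = 720 mV, V(1.3 I1) = 548 mV
        a = np.array([[1.0, -1.0], [1.0, -1.3]])  # [v_reset, alpha*I1]
        b = np.array([0.720, 0.548])
        v_reset, alpha_i1 = np.linalg.solve(a, b)
        assert alpha_i1 == pytest.approx(0.57333, abs=1e-5)
        assert v_reset == pytest.approx(1.29333, abs=1e-5)
        assert P.v_reset == pytest.approx(v_reset)
        assert P.alpha * 1.0 == pytest.approx(alpha_i1)
        assert aps_voltage(1.0, P) == pytest.approx(0.720)
        assert aps_voltage(1.3, P) == pytest.approx(0.548)

    def test_huge_intensity_clamps_to_zero(self):
        assert aps_voltage(1e6, P) == 0.0

    def test_rail_clamp_upper(self):
        p = PixelParams(v_reset=2.0)
        assert aps_voltage(0.0, p) == p.vdd_pixel


class TestSampler:
    def test_no_change_gives_mid_rail(self):
        assert sampler_subtract(0.6, 0.6, P) == pytest.approx(0.5 * P.vdd)

    def test_printed_anchor_transition(self):
        # 720 mV -> 548 mV at V_DD = 0.8 V stores 228 mV
        assert sampler_subtract(0.720, 0.548, P) == pytest.approx(0.228)

    @given(st.floats(0, 1.5), st.floats(0, 1.5))
    def test_antisymmetry_about_mid_rail(self, a, b):
        up = sampler_subtract(a, b, P)
        dn = sampler_subtract(b, a, P)
        assert up + dn == pytest.approx(P.vdd)


class TestThreshold:
    def test_mid_rail_is_silent(self):
        assert threshold_bipolar(0.5 * P.vdd, P) == 0

    def test_boundaries_inclusive_and_mirrored(self):
        delta = P.theta * P.alpha * 1.0
        assert threshold_bipolar(0.5 * P.vdd - delta, P, intensity_ref=1.0) == 1
        assert threshold_bipolar(0.5 * P.vdd + delta, P, intensity_ref=1.0) == -1
        assert threshold_bipolar(0.5 * P.vdd - 0.9 * delta, P, intensity_ref=1.0) == 0

    def test_anchor_transition_fires_on(self):
        # V_C = 228 mV sits exactly at the 30 % trip calibrated at I1 = 1
        assert threshold_bipolar(0.228, P, intensity_ref=1.0) == 1


class TestIdealBackend:
    @pytest.mark.parametrize(
        "i0,i1,label",
        [
            (100.0, 130.0, 1),           # exactly +30 %: inclusive ON
            (100.0, 100.0 * (1.3 - 1e-6), 0),  # just below the boundary
            (100.0, 70.0, -1),           # exactly -30 %: inclusive OFF
            (100.0, 100.0, 0),
        ],
    )
    def test_contrast_rule(self, i0, i1, label):
        bip = detect_bipolar_ideal(stack_1px([i0, i1]), theta=0.30)
        assert bip.data[0, 0, 0] == label

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="two frames"):
            detect_bipolar_ideal(stack_1px([1.0]))

    def test_zero_light_denominator_uses_floor(self):
        bip = detect_bipolar_ideal(stack_1px([0.0, 1.0]), theta=0.30)
        assert bip.data[0, 0, 0] == 1

    @given(st.lists(st.floats(1.0, 1e3), min_size=3, max_size=8))
    def test_polarity_matches_intensity_direction(self, values):
        values = np.sort(values)
        bip = detect_bipolar_ideal(stack_1px(values))
        assert not np.any(bip.data == -1)
        bip_dn = detect_bipolar_ideal(stack_1px(values[::-1].copy()))
        assert not np.any(bip_dn.data == 1)


class TestBackendAgreement:
    @pytest.mark.parametrize("name", rs.SCENARIOS)
    def test_aps_analog_matches_ideal_away_from_boundary(self, name, scene_cache):
        stack, _ = scene_cache(name)
        ideal = detect_bipolar_ideal(stack, P.theta, P.eps_dark)
        analog = detect_bipolar_aps(stack, P, calibration="local")
        prev = stack.frames[:-1]
        contrast = (stack.frames[1:] - prev) / np.maximum(prev, P.eps_dark)
        decided = np.abs(np.abs(contrast) - P.theta) > 1e-3
        assert np.array_equal(ideal.data[decided], analog.data[decided])


class TestDvs:
    def test_log_reference_zero(self):
        p = PixelParams(i_ref=2.0)
        assert dvs_log_voltage(2.0 - p.eps_dark, p) == pytest.approx(0.0)

    def test_log_step_closed_form(self):
        # a 1.3x contrast on a 70 mV/e-fold photoreceptor is 18.36 mV
        dv = dvs_log_voltage(1.3, P) - dvs_log_voltage(1.0, P)
        assert dv == pytest.approx(0.070 * math.log(1.3), abs=1e-6)
        assert dv * 1e3 == pytest.approx(18.365, abs=1e-2)

    def test_log_additivity_of_doublings(self):
        v1 = dvs_log_voltage(100.0, P)
        v4 = dvs_log_voltage(400.0, P)
        assert v4 - v1 == pytest.approx(2 * P.m_log * math.log(2), abs=1e-6)

    def test_constant_intensity_no_events(self):
        ev = dvs_events(stack_1px([5.0, 5.0, 5.0]), P)
        assert len(ev) == 0

    def test_ramp_event_count(self):
        # 100 -> 300 at theta = 0.3: floor(ln 3 / ln 1.3) = 4 ON events
        ev = dvs_events(stack_1px([100.0, 300.0]), P)
        assert len(ev) == 4
        assert np.all(ev.polarity == 1)

    def test_reference_update_semantics(self):
        # 100 -> 130 -> 100: one ON then one OFF (reference steps once)
        ev = dvs_events(stack_1px([100.0, 130.0, 100.0]), P)
        assert ev.polarity.tolist() == [1, -1]

    @pytest.mark.parametrize("ratio", [1.27, 1.35, 1.9, 3.1, 6.0])
    @pytest.mark.parametrize("theta", [0.2, 0.3, 0.5])
    def test_monotone_count_oracle(self, ratio, theta):
        p = PixelParams(theta=theta)
        expect = math.floor(math.log(ratio) / math.log1p(theta))
        up = dvs_events(stack_1px([50.0, 50.0 * ratio]), p)
        dn = dvs_events(stack_1px([50.0 * ratio, 50.0]), p)
        assert len(up) == expect and np.all(up.polarity == 1)
        assert len(dn) == expect and np.all(dn.polarity == -1)

    def test_timestamps_interpolate_within_interval(self):
        ev = dvs_events(stack_1px([100.0, 300.0], period=1000.0), P)
        assert np.all((ev.t_us > 0) & (ev.t_us <= 1000.0))
        assert np.all(np.diff(ev.t_us) > 0)  # successive crossings, ordered

    def test_multi_transition_counts_accumulate(self):
        # two consecutive +30 % steps: one event each, no drift explosion
        ev = dvs_events(stack_1px([100.0, 130.0, 169.0]), P)
        assert ev.polarity.tolist() == [1, 1]
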