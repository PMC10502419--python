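"""Behavioral Monte-Carlo engine for device-variation analysis.

Mismatch is injected *behaviorally*, not through transistor models:

* one global supply draw per chip instance, ``vdd_i ~ N(vdd, sigma_vdd)``;
* per-comparator trip-point offsets, ``N(0, sigma_trip)``;
* per-device conductance/gain multipliers, ``LogNormal(0, sigma_strength)``;
* per-pixel photoreceptor offsets for the DVS log front end,
  ``N(0, sigma_pr)``.

All draws derive from a single seed.  Standard-normal deviates are drawn
first and scaled by the sigmas afterwards, so sweeping a sigma with a
fixed seed reuses the same underlying randomness (common random numbers)
— the device-by-device margins, and hence the fraction-correct summary,
are then monotone in each sigma.

Four pipeline stages can be placed under variation: ``bipolar_aps`` and
``bipolar_dvs`` (the contrast-threshold experiment on a single pixel),
and ``oms`` / ``ld`` (a full scenario evaluated per sample with perturbed
pull strengths, trip points and supply).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stimuli
from .feature_ld import LDParams
from .feature_oms import AnalogParams
from .phototransduction import PixelParams, detect_bipolar_ideal, dvs_log_voltage
from .receptive_field import RFMap, build_rfmap

__all__ = ["MCSpec", "DeviceDraws", "MCResult", "sample_devices", "run_mc"]

_DEVICE_CLASSES = ("pixels", "comparators", "transistors")
_STAGES = ("bipolar_aps", "bipolar_dvs", "oms", "ld")


@dataclass
class MCSpec:
    """Monte-Carlo experiment specification.

    ``sigma_vdd`` defaults to the 10 mV supply standard deviation of the
    reference variation experiment; ``sigma_pr`` to the 43.2 mV
    photoreceptor offset scale.  ``sigma_trip`` and ``sigma_strength``
    are free behavioral parameters (device-level mismatch distributions
    are foundry data); their defaults leave the nominal 30 %-contrast
    experiment comfortable margin.
    """

    n_samples: int = 1000
    sigma_vdd: float = 0.010
    sigma_trip: float = 0.005
    sigma_strength: float = 0.05
    sigma_pr: float = 0.0432
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("sigma_vdd", "sigma_trip", "sigma_strength", "sigma_pr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DeviceDraws:
    """Per-sample drawn parameters (offsets and multipliers)."""

    vdd_offset: np.ndarray            # (n_samples,)
    trip_offset: np.ndarray           # (n_samples, n_comparators)
    strength: np.ndarray              # (n_samples, n_transistors), multiplicative
    pr_offset: np.ndarray             # (n_samples, n_pixels)


@dataclass
class MCResult:
    """Per-sample outcomes plus recomputable summaries."""

    spec: MCSpec
    stage: str
    draws: DeviceDraws
    samples: pd.DataFrame
    summary: dict = field(default_factory=dict)


def sample_devices(spec: MCSpec, topology: dict[str, int]) -> DeviceDraws:
    """Draw all per-sample device parameters for a named topology.

    ``topology`` maps device classes (``pixels``, ``comparators``,
    ``transistors``) to counts.  Unknown classes raise.  Identical spec
    and topology give identical draws; the same seed with different
    sigmas reuses the same standard-normal deviates.
    """
    unknown = set(topology) - set(_DEVICE_CLASSES)
    if unknown:
        raise ValueError(
            f"unknown device class(es) {sorted(unknown)}; "
            f"expected a subset of {_DEVICE_CLASSES}"
        )
    n = spec.n_samples
    n_pix = int(topology.get("pixels", 0))
    n_cmp = int(topology.get("comparators", 0))
    n_dev = int(topology.get("transistors", 0))
    rng = np.random.default_rng(spec.seed)
    z_vdd = rng.standard_normal(n)
    z_trip = rng.standard_normal((n, n_cmp))
    z_dev = rng.standard_normal((n, n_dev))
    z_pr = rng.standard_normal((n, n_pix))
    return DeviceDraws(
        vdd_offset=spec.sigma_vdd * z_vdd,
        trip_offset=spec.sigma_trip * z_trip,
        strength=np.exp(spec.sigma_strength * z_dev),
        pr_offset=spec.sigma_pr * z_pr,
    )


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _run_bipolar_aps(scenario: dict, spec: MCSpec, p: PixelParams) -> MCResult:
    """30 %-contrast experiment on one APS pixel: fraction emitting ON."""
    i1 = float(scenario.get("i1", 1.0))
    contrast = float(scenario.get("contrast", p.theta))
    i2 = i1 * (1.0 + contrast)
    draws = sample_devices(
        spec, {"pixels": 1, "comparators": 2, "transistors": 1}
    )
    dvdd = draws.vdd_offset
    gain = draws.strength[:, 0]
    # supply offset shifts the reset level; conversion-gain mismatch scales
    # the light-dependent drop; both pixel samples share the chip instance
    v1 = np.clip(p.v_reset + dvdd - p.alpha * gain * i1, 0.0, p.vdd_pixel)
    v2 = np.clip(p.v_reset + dvdd - p.alpha * gain * i2, 0.0, p.vdd_pixel)
    vdd_i = p.vdd + dvdd
    v_c = 0.5 * vdd_i + (v2 - v1)
    on = v_c <= 0.5 * vdd_i - p.delta_trip + draws.trip_offset[:, 0]
    samples = pd.DataFrame(
        {
            "vdd": vdd_i,
            "v_px_1": v1,
            "v_px_2": v2,
            "v_c": v_c,
            "on": on,
        }
    )
    summary = {
        "fraction_correct": float(on.mean()),
        "mean_v_px_1_mv": float(v1.mean() * 1e3),
        "mean_v_px_2_mv": float(v2.mean() * 1e3),
        "sd_vdd_mv": float(vdd_i.std(ddof=1) * 1e3) if spec.n_samples > 1 else 0.0,
        "mean_v_c_mv": float(v_c.mean() * 1e3),
    }
    return MCResult(spec, "bipolar_aps", draws, samples, summary)


def _run_bipolar_dvs(scenario: dict, spec: MCSpec, p: PixelParams) -> MCResult:
    """30 %-contrast experiment on one DVS pixel.

    The per-pixel photoreceptor offset widens the log-voltage
    distributions of the two samples (they overlap across chip
    instances) but cancels in the temporal difference, which the
    amplifier then carries across the comparator threshold.
    """
    i1 = float(scenario.get("i1", 1.0))
    contrast = float(scenario.get("contrast", p.theta))
    i2 = i1 * (1.0 + contrast)
    draws = sample_devices(
        spec, {"pixels": 1, "comparators": 1, "transistors": 1}
    )
    pr = draws.pr_offset[:, 0]
    gain = draws.strength[:, 0]
    v_log_1 = dvs_log_voltage(i1, p) + pr
    v_log_2 = dvs_log_voltage(i2, p) + pr
    amp_out = p.amp_gain * gain * (v_log_2 - v_log_1)
    threshold = p.dvs_trip_margin * p.amp_gain * p.log_step + draws.trip_offset[:, 0]
    on = amp_out >= threshold
    samples = pd.DataFrame(
        {
            "v_log_1": v_log_1,
            "v_log_2": v_log_2,
            "amp_out": amp_out,
            "on": on,
        }
    )
    dv = v_log_2 - v_log_1
    summary = {
        "fraction_correct": float(on.mean()),
        "sd_v_log_mv": float(v_log_1.std(ddof=1) * 1e3) if spec.n_samples > 1 else 0.0,
        "mean_diff_mv": float(dv.mean() * 1e3),
        "min_diff_mv": float(dv.min() * 1e3),
    }
    return MCResult(spec, "bipolar_dvs", draws, samples, summary)


def _field_slots(rf: RFMap, sets: dict) -> tuple[dict, int]:
    """Assign one transistor slot per (field, pixel) membership."""
    slots = {}
    offset = 0
    for f in rf.field_ids:
        size = sets[f].size
        slots[f] = np.arange(offset, offset + size)
        offset += size
    return slots, offset


def _run_field_stage(
    stage: str,
    scenario_name: str,
    spec: MCSpec,
    pixel_params: PixelParams,
    analog_params: AnalogParams | None,
    ld_params: LDParams | None,
    grid: tuple[int, int],
    donor_fraction: float,
    size: tuple[int, int],
) -> MCResult:
    stack, truth = stimuli.scenario(scenario_name, seed=spec.seed, size=size)
    bip = detect_bipolar_ideal(stack, pixel_params.theta, pixel_params.eps_dark)
    rf = build_rfmap(*size, *grid, donor_fraction=donor_fraction)
    k = bip.n_transitions
    n = spec.n_samples
    fields = rf.field_ids

    if stage == "oms":
        p = analog_params or AnalogParams()
        c_slots, n_c_dev = _field_slots(rf, rf.centers)
        s_slots, n_s_dev = _field_slots(rf, rf.surrounds)
        draws = sample_devices(
            spec,
            {"comparators": len(fields), "transistors": n_c_dev + n_s_dev},
        )
        m_c = draws.strength[:, :n_c_dev]
        m_s = draws.strength[:, n_c_dev:]
        act = bip.activity().reshape(k, -1)
        vdd_i = p.vdd + draws.vdd_offset
        # the buffer trip tracks the supply; keep its design fraction
        v_th = (p.v_th_oms / p.vdd) * vdd_i[:, None] + draws.trip_offset
        v_int = np.empty((n, len(fields), k))
        for fi, f in enumerate(fields):
            act_c = act[:, rf.centers[f]]
            act_s = act[:, rf.surrounds[f]]
            for t in range(k):
                g_u = rf.w_c[f] * m_c[:, c_slots[f][act_c[t]]].sum(axis=1)
                g_d = rf.w_s[f] * m_s[:, s_slots[f][act_s[t]]].sum(axis=1)
                v_int[:, fi, t] = (g_u * vdd_i + p.g0 * vdd_i / 2.0) / (
                    g_u + g_d + p.g0
                )
        spikes = v_int > v_th[:, :, None]
        any_spike = spikes.any(axis=(1, 2))
        samples = pd.DataFrame(
            {
                "vdd": vdd_i,
                "max_v_int": v_int.max(axis=(1, 2)),
                "n_spikes": spikes.sum(axis=(1, 2)),
                "any_spike": any_spike,
            }
        )
        summary = {
            "fraction_silent": float((~any_spike).mean()),
            "fraction_spiking": float(any_spike.mean()),
            "mean_max_v_int_mv": float(v_int.max(axis=(1, 2)).mean() * 1e3),
        }
        return MCResult(spec, stage, draws, samples, summary)

    # LD: one ON and one OFF device per territory pixel
    p = ld_params or LDParams()
    terr_slots, n_pix_dev = _field_slots(rf, rf.territories)
    draws = sample_devices(
        spec, {"comparators": len(fields), "transistors": 2 * n_pix_dev}
    )
    m_on = draws.strength[:, :n_pix_dev]
    m_off = draws.strength[:, n_pix_dev:]
    on = (bip.data > 0).reshape(k, -1)
    off = (bip.data < 0).reshape(k, -1)
    vdd_i = p.vdd + draws.vdd_offset
    up_frac = p.v_th_up / p.vdd
    dn_frac = p.v_th_dn / p.vdd
    v_th_up = up_frac * vdd_i[:, None] + draws.trip_offset
    v_th_dn = dn_frac * vdd_i[:, None] - draws.trip_offset
    v_int = np.empty((n, len(fields), k))
    for fi, f in enumerate(fields):
        on_f = on[:, rf.territories[f]]
        off_f = off[:, rf.territories[f]]
        for t in range(k):
            g_u = p.w_ld * m_on[:, terr_slots[f][on_f[t]]].sum(axis=1)
            g_d = p.w_ld * m_off[:, terr_slots[f][off_f[t]]].sum(axis=1)
            v_int[:, fi, t] = (g_u * vdd_i + p.g0 * vdd_i / 2.0) / (
                g_u + g_d + p.g0
            )
    high = v_int > v_th_up[:, :, None]
    low = v_int < v_th_dn[:, :, None]
    any_high = high.any(axis=(1, 2))
    any_low = low.any(axis=(1, 2))
    samples = pd.DataFrame(
        {
            "vdd": vdd_i,
            "max_v_int": v_int.max(axis=(1, 2)),
            "min_v_int": v_int.min(axis=(1, 2)),
            "any_high": any_high,
            "any_low": any_low,
        }
    )
    summary = {
        "fraction_silent": float((~(any_high | any_low)).mean()),
        "fraction_high": float(any_high.mean()),
        "fraction_low": float(any_low.mean()),
    }
    return MCResult(spec, stage, draws, samples, summary)


def run_mc(
    stage: str,
    scenario: str | dict | None = None,
    spec: MCSpec | None = None,
    pixel_params: PixelParams | None = None,
    analog_params: AnalogParams | None = None,
    ld_params: LDParams | None = None,
    grid: tuple[int, int] = (3, 3),
    donor_fraction: float = 0.25,
    size: tuple[int, int] = (63, 63),
) -> MCResult:
    """Run a pipeline stage under Monte-Carlo device variation.

    Parameters
    ----------
    stage : {"bipolar_aps", "bipolar_dvs", "oms", "ld"}
        Which stage to perturb.  The bipolar stages take a scenario dict
        ``{"i1": ..., "contrast": ...}`` (defaults: unit intensity at the
        configured contrast sensitivity); the field stages take a
        scenario *name* from :mod:`retinasim.stimuli`.
    spec : MCSpec
        Sample count, sigmas and seed.  Defaults to the reference
        1000-sample experiment.

    With all sigmas at zero every sample reproduces the deterministic
    pipeline exactly.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; one of {_STAGES}")
    spec = spec or MCSpec()
    p = pixel_params or PixelParams()
    if stage == "bipolar_aps":
        return _run_bipolar_aps(dict(scenario or {}), spec, p)
    if stage == "bipolar_dvs":
        return _run_bipolar_dvs(dict(scenario or {}), spec, p)
    if not isinstance(scenario, str):
        raise ValueError(f"stage {stage!r} requires a scenario name")
    return _run_field_stage(
        stage, scenario, spec, p, analog_params, ld_params,
        grid, donor_fraction, size,
    )
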