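"""ON/OFF bipolar-signal generation from intensity frame stacks.

Two backends model the first stage of retina-inspired change detection:

* **APS** (synchronous): a conventional 3-transistor active pixel whose
  output voltage falls linearly with light, a switched-capacitor sampler
  that stores the difference of two consecutive frames offset by
  ``V_DD / 2``, and an inverter-based thresholding stage that emits an ON
  (OFF) signal when the light intensity rose (fell) past the contrast
  threshold.
* **DVS** (asynchronous): a logarithmic photoreceptor followed by a
  difference amplifier; a pixel emits one event per threshold crossing of
  its log-voltage relative to a per-pixel reference that steps by exactly
  one threshold per event (standard event-camera semantics).

The **ideal** backend ``detect_bipolar_ideal`` applies the defining
contrast rule directly — ON iff ``(I_k - I_{k-1}) / I_{k-1} >= theta``,
boundary inclusive — and serves as the specification of intent that the
analog paths approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BipolarMap, EventStream, FrameStack

__all__ = [
    "PixelParams",
    "aps_voltage",
    "sampler_subtract",
    "threshold_bipolar",
    "detect_bipolar_aps",
    "detect_bipolar_ideal",
    "dvs_log_voltage",
    "dvs_events",
]

# Two-point calibration of the APS transfer curve from its printed mean
# operating points: V(I=1) = 720 mV and V(I=1.3) = 548 mV give
# alpha = 172 mV / 0.3 per intensity unit and v_reset = 720 mV + alpha.
_ALPHA_DEFAULT = 0.172 / 0.3
_VRESET_DEFAULT = 0.720 + _ALPHA_DEFAULT

#: Relative tolerance (in units of one threshold step) applied to the DVS
#: crossing count so that trajectories landing exactly on a threshold are
#: counted inclusively despite floating-point log round-off.
_DVS_STEP_RTOL = 1e-6


@dataclass
class PixelParams:
    """Electrical parameters of the bipolar-signal front end.

    Parameters
    ----------
    vdd : float
        Core supply, volts.  0.8 V is a 22 nm-class core rail, consistent
        with comparator trip points quoted relative to ``V_DD / 2``.
    vdd_pixel : float
        APS pixel supply rail; may exceed ``vdd`` (the calibrated reset
        level of 1.293 V requires a higher pixel rail, here 1.5 V).
    v_reset : float
        APS reset level, volts; the zero-light pixel output.
    alpha : float
        APS conversion gain, volts per intensity unit:
        ``V_PX = clamp(v_reset - alpha * I, 0, vdd_pixel)``.
    theta : float
        Contrast sensitivity — the minimum relative luminance change
        between consecutive frames that elicits a bipolar signal.
    i_trip_ref : float
        Reference intensity at which the APS comparator trip offset is
        calibrated in ``global`` mode (``delta = theta * alpha *
        i_trip_ref``).  A two-inverter thresholder has fixed trip points,
        so the analog APS path is only approximately contrast-scaling;
        the default sits at the dim end of the operating range (0.7 of
        the unit stimulus) so stimuli at the specified contrast carry
        decision margin.
    m_log : float
        DVS log-photoreceptor slope, volts per e-fold of intensity.
    i_ref : float
        DVS log reference intensity (``V_LOG = 0`` at ``I + eps = i_ref``).
    amp_gain : float
        DVS difference-amplifier gain (dimensionless).
    dvs_trip_margin : float
        Design margin of the DVS comparator: it trips at this fraction of
        the amplified nominal threshold step (used by the Monte-Carlo
        experiments; the event generator itself uses the exact step).
    eps_dark : float
        Intensity floor added inside logs and ratio denominators so both
        stay defined at zero light.
    """

    vdd: float = 0.8
    vdd_pixel: float = 1.5
    v_reset: float = _VRESET_DEFAULT
    alpha: float = _ALPHA_DEFAULT
    theta: float = 0.30
    i_trip_ref: float = 0.7
    m_log: float = 0.070
    i_ref: float = 1.0
    amp_gain: float = 20.0
    dvs_trip_margin: float = 0.7
    eps_dark: float = 1e-6

    def __post_init__(self) -> None:
        if not self.vdd > 0:
            raise ValueError("vdd must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if not self.m_log > 0:
            raise ValueError("m_log must be positive")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.eps_dark > 0:
            raise ValueError("eps_dark must be positive")

    @property
    def delta_trip(self) -> float:
        """Global-mode comparator trip offset from ``V_DD / 2``, volts."""
        return self.theta * self.alpha * self.i_trip_ref

    @property
    def log_step(self) -> float:
        """DVS threshold step in the log-voltage domain, volts."""
        return self.m_log * np.log1p(self.theta)


def aps_voltage(intensity: np.ndarray, p: PixelParams) -> np.ndarray:
    """APS pixel output: inversely linear in light, clamped to the rail.

    ``V_PX = clamp(v_reset - alpha * I, 0, vdd_pixel)`` elementwise.
    """
    v = p.v_reset - p.alpha * np.asarray(intensity, dtype=float)
    return np.clip(v, 0.0, p.vdd_pixel)


def sampler_subtract(v_prev, v_curr, p: PixelParams):
    """Switched-capacitor sampler output.

    Stores the difference of two consecutive pixel samples offset by a
    constant ``V_DD / 2``: ``V_C = 0.5 vdd + (v_curr - v_prev)``.
    """
    return 0.5 * p.vdd + (np.asarray(v_curr, float) - np.asarray(v_prev, float))


def threshold_bipolar(
    v_c, p: PixelParams, intensity_ref=None
) -> np.ndarray:
    """Inverter-comparator decision on the sampler output.

    The APS voltage *falls* when light rises, so ON corresponds to
    ``V_C <= 0.5 vdd - delta`` and OFF to ``V_C >= 0.5 vdd + delta``
    (both boundaries inclusive), with ``delta = theta * alpha * I_ref``.

    ``intensity_ref`` may be a scalar or a per-pixel array; it defaults to
    the globally calibrated ``p.i_trip_ref``.
    """
    v_c = np.asarray(v_c, dtype=float)
    ref = p.i_trip_ref if intensity_ref is None else intensity_ref
    delta = p.theta * p.alpha * np.maximum(np.asarray(ref, float), p.eps_dark)
    out = np.zeros(np.broadcast(v_c, delta).shape, dtype=np.int8)
    out[v_c <= 0.5 * p.vdd - delta] = 1
    out[v_c >= 0.5 * p.vdd + delta] = -1
    return out


def detect_bipolar_aps(
    stack: FrameStack, p: PixelParams | None = None, calibration: str = "local"
) -> BipolarMap:
    """Behavioral-analog APS path: pixel -> sampler -> thresholding.

    ``calibration`` selects the comparator trip-offset reference:

    * ``"local"`` — per pixel, the previous frame's intensity, which makes
      the analog decision algebraically equivalent to the ideal contrast
      rule away from the clamp rails;
    * ``"global"`` — the fixed ``p.i_trip_ref``, mirroring the hardware
      reality of one trip point shared by the whole array.
    """
    p = p or PixelParams()
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to detect contrast changes")
    if calibration not in ("local", "global"):
        raise ValueError("calibration must be 'local' or 'global'")
    v = aps_voltage(stack.frames, p)
    out = np.empty((stack.n_frames - 1,) + stack.shape, dtype=np.int8)
    for k in range(1, stack.n_frames):
        v_c = sampler_subtract(v[k - 1], v[k], p)
        ref = stack.frames[k - 1] if calibration == "local" else None
        out[k - 1] = threshold_bipolar(v_c, p, intensity_ref=ref)
    return BipolarMap(out, stack.frame_period_us)


def detect_bipolar_ideal(
    stack: FrameStack, theta: float = 0.30, eps_dark: float = 1e-6
) -> BipolarMap:
    """Idealized contrast-rule backend (the specification of intent).

    Per pixel and transition ``k``:
    ON iff ``(I_k - I_{k-1}) / max(I_{k-1}, eps) >= theta``;
    OFF iff ``(I_{k-1} - I_k) / max(I_{k-1}, eps) >= theta``;
    boundary inclusive.  The denominator is the previous frame — the
    causal choice of reference luminance.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to detect contrast changes")
    prev = stack.frames[:-1]
    curr = stack.frames[1:]
    ratio = (curr - prev) / np.maximum(prev, eps_dark)
    out = np.zeros_like(ratio, dtype=np.int8)
    out[ratio >= theta] = 1
    out[-ratio >= theta] = -1
    return BipolarMap(out, stack.frame_period_us)


def dvs_log_voltage(intensity, p: PixelParams) -> np.ndarray:
    """Logarithmic photoreceptor output ``V_LOG = m_log ln((I + eps)/i_ref)``."""
    i = np.asarray(intensity, dtype=float)
    return p.m_log * np.log((i + p.eps_dark) / p.i_ref)


def dvs_events(stack: FrameStack, p: PixelParams | None = None) -> EventStream:
    """Asynchronous event generation from a frame stack.

    Each pixel keeps a reference log-voltage (initialized at frame 0).
    Whenever the current log-voltage deviates from the reference by at
    least one threshold step ``m_log * ln(1 + theta)`` the pixel emits an
    ON/OFF event and the reference moves by exactly one step, so a large
    excursion yields multiple events.  Timestamps are placed by linear
    interpolation of the log-voltage within the frame interval; ties are
    broken in raster order.
    """
    p = p or PixelParams()
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to generate events")
    v = dvs_log_voltage(stack.frames, p)
    h, w = stack.shape
    step = p.log_step
    ref = v[0].copy()
    period = stack.frame_period_us

    ts, xs, ys, ps = [], [], [], []
    for k in range(1, stack.n_frames):
        d = v[k] - ref
        n = np.floor(np.abs(d) / step + _DVS_STEP_RTOL).astype(int)
        yy, xx = np.nonzero(n)
        if yy.size:
            counts = n[yy, xx]
            sign = np.sign(d[yy, xx]).astype(np.int8)
            # expand one row per event, in raster-major order
            rep_y = np.repeat(yy, counts)
            rep_x = np.repeat(xx, counts)
            rep_s = np.repeat(sign, counts)
            # event index j = 1..count within each pixel
            j = np.arange(counts.sum()) - np.repeat(
                np.cumsum(counts) - counts, counts
            ) + 1
            level = ref[rep_y, rep_x] + rep_s * j * step
            v_prev = v[k - 1][rep_y, rep_x]
            v_curr = v[k][rep_y, rep_x]
            dv = v_curr - v_prev
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(dv != 0, (level - v_prev) / dv, 1.0)
            frac = np.clip(frac, 0.0, 1.0)
            ts.append((k - 1 + frac) * period)
            xs.append(rep_x)
            ys.append(rep_y)
            ps.append(rep_s)
            ref[yy, xx] += sign * counts * step
    if ts:
        t = np.concatenate(ts)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        pol = np.concatenate(ps)
        order = np.lexsort((x, y, t))
        t, x, y, pol = t[order], x[order], y[order], pol[order]
    else:
        t = np.empty(0)
        x = y = np.empty(0, dtype=int)
        pol = np.empty(0, dtype=np.int8)
    return EventStream(t, x, y, pol, shape=(h, w), frame_period_us=period)
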