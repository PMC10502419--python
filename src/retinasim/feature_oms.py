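"""Object-motion-sensitivity (OMS) feature-spike generation.

Per receptive field, active *center* devices pull a shared integration
node toward the supply while active *surround* devices pull it toward
ground; a weak keeper holds the quiescent node at ``V_DD / 2``.  The
steady-state node voltage is the resistive-divider value

    V_INT = (w_c n_c V_DD + g0 V_DD / 2) / (w_c n_c + w_s n_s + g0)

and a high-skewed buffer emits an OMS spike when ``V_INT`` exceeds its
trip point (strictly — ties produce no spike).  Under global motion with
balanced weights, pull-up and pull-down cancel and the node stays at
``V_DD / 2``; differential motion in the center drives it up.

OMS pools ON and OFF bipolar signals alike: any contrast change counts
as an activation.  Asynchronous (event) input is latched once per frame
period; a pixel with at least one event in the window counts once.

An optional RC transient mode models the finite integration capacitor:
within each constant-activation segment the node relaxes exponentially
toward the divider value with ``tau = c_int / (G_up + G_down + g0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BipolarMap, EventStream, latch_events
from .receptive_field import RFMap

__all__ = ["AnalogParams", "oms_vint", "oms_spike", "oms_pipeline", "oms_transient"]

SPIKE_COLUMNS = ["t", "field_row", "field_col", "feature", "side", "v_int"]


@dataclass
class AnalogParams:
    """Electrical parameters of the OMS integration node and buffer.

    ``v_th_oms`` defaults to ``0.55 * vdd`` — a high-skewed buffer whose
    trip sits above the quiescent ``V_DD / 2``.  ``g0`` is the keeper
    conductance to the mid-rail reference; it pins the idle node voltage
    and sets the circuit's sensitivity scale (all conductances are in the
    same arbitrary units).  ``c_int`` only matters in ``rc`` mode, where
    ``tau = c_int / G_total`` is expressed in the schedule's time unit.
    """

    vdd: float = 0.8
    g0: float = 1.0
    w_c: float = 1.0
    w_s: float = 1.0
    v_th_oms: float | None = None
    c_int: float = 2.0
    tau_mode: str = "steady_state"

    def __post_init__(self) -> None:
        if not self.vdd > 0:
            raise ValueError("vdd must be positive")
        if not self.g0 > 0:
            raise ValueError("g0 must be positive")
        if self.v_th_oms is None:
            self.v_th_oms = 0.55 * self.vdd
        if not 0 < self.v_th_oms < self.vdd:
            raise ValueError("v_th_oms must lie strictly inside (0, vdd)")
        if self.tau_mode not in ("steady_state", "rc"):
            raise ValueError("tau_mode must be 'steady_state' or 'rc'")


def oms_vint(n_c, n_s, p: AnalogParams, w_c: float | None = None, w_s: float | None = None):
    """Steady-state integration-node voltage of the OMS divider.

    ``n_c`` / ``n_s`` are active center / surround device counts (scalars
    or arrays).  Weights default to ``p.w_c`` / ``p.w_s`` and are
    overridden per field by the pipeline.
    """
    w_c = p.w_c if w_c is None else w_c
    w_s = p.w_s if w_s is None else w_s
    g_up = w_c * np.asarray(n_c, dtype=float)
    g_dn = w_s * np.asarray(n_s, dtype=float)
    return (g_up * p.vdd + p.g0 * p.vdd / 2.0) / (g_up + g_dn + p.g0)


def oms_spike(v_int, p: AnalogParams):
    """Skewed-buffer decision: spike iff ``v_int > v_th_oms`` (strict)."""
    return np.asarray(v_int, dtype=float) > p.v_th_oms


def _activity_counts(activity: np.ndarray, rf: RFMap):
    """Per-field active center/surround counts for each transition."""
    k = activity.shape[0]
    flat = activity.reshape(k, -1)
    n_c = {f: flat[:, rf.centers[f]].sum(axis=1) for f in rf.field_ids}
    n_s = {f: flat[:, rf.surrounds[f]].sum(axis=1) for f in rf.field_ids}
    return n_c, n_s


def oms_pipeline(
    bipolar: BipolarMap | EventStream,
    rf: RFMap,
    p: AnalogParams | None = None,
) -> pd.DataFrame:
    """Evaluate the OMS circuit per field for every frame transition.

    Returns a DataFrame with one row per (transition, field):
    ``t`` (transition index), ``field_row``, ``field_col``, ``feature``
    (``"OMS"``), ``side`` (``"high"`` for a spike else ``"none"``) and
    ``v_int`` in volts.  Spikes are the rows with ``side == "high"``.
    """
    p = p or AnalogParams()
    if not rf.w_s:
        raise ValueError("RFMap has no weights; call balanced_weights first")
    if isinstance(bipolar, EventStream):
        if bipolar.shape != (rf.height, rf.width):
            raise ValueError(
                f"event geometry {bipolar.shape} does not match the "
                f"RFMap geometry {(rf.height, rf.width)}"
            )
        t_max = bipolar.t_us.max() if len(bipolar) else 0.0
        k = max(1, int(np.ceil(t_max / bipolar.frame_period_us)))
        on, off = latch_events(bipolar, k)
        activity = on | off
    else:
        if bipolar.shape != (rf.height, rf.width):
            raise ValueError(
                f"bipolar geometry {bipolar.shape} does not match the "
                f"RFMap geometry {(rf.height, rf.width)}"
            )
        activity = bipolar.activity()
    n_c, n_s = _activity_counts(activity, rf)
    k = activity.shape[0]
    rows = []
    for f in rf.field_ids:
        v = oms_vint(n_c[f], n_s[f], p, w_c=rf.w_c[f], w_s=rf.w_s[f])
        spikes = oms_spike(v, p)
        for t in range(k):
            rows.append(
                (t + 1, f[0], f[1], "OMS", "high" if spikes[t] else "none", v[t])
            )
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    return df.sort_values(["t", "field_row", "field_col"], ignore_index=True)


def oms_transient(
    schedule: list[tuple[float, float, float]],
    p: AnalogParams | None = None,
    samples_per_segment: int = 50,
    w_c: float | None = None,
    w_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """RC transient of the integration node under a piecewise schedule.

    ``schedule`` is a list of ``(duration, n_c, n_s)`` segments.  Within
    each segment the node relaxes exponentially toward the steady-state
    divider value with ``tau = c_int / (G_up + G_down + g0)``, continuous
    across segment boundaries.  The trace starts at the quiescent
    ``V_DD / 2``.

    Returns ``(times, v_int)`` sampled densely within each segment
    (segment boundaries included).
    """
    p = p or AnalogParams()
    times, trace = [], []
    t0 = 0.0
    v0 = p.vdd / 2.0
    wc = p.w_c if w_c is None else w_c
    ws = p.w_s if w_s is None else w_s
    for duration, n_c, n_s in schedule:
        if duration < 0:
            raise ValueError("segment durations must be nonnegative")
        g_total = wc * n_c + ws * n_s + p.g0
        v_ss = float(oms_vint(n_c, n_s, p, w_c=wc, w_s=ws))
        tau = p.c_int / g_total
        tt = np.linspace(0.0, duration, samples_per_segment)
        vv = v_ss + (v0 - v_ss) * np.exp(-tt / tau)
        times.append(t0 + tt)
        trace.append(vv)
        t0 += duration
        v0 = vv[-1]
    return np.concatenate(times), np.concatenate(trace)
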