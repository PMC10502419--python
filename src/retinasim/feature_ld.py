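"""Looming-detection (LD) feature-spike generation.

Per receptive field, every pixel drives a *pair* of devices on a shared
integration node: ON bipolar signals pull toward the supply, OFF signals
pull toward ground, with equal conductance ``w_ld`` on both paths and a
keeper ``g0`` holding the quiescent node at ``V_DD / 2``:

    V_INT = (w_ld n_on V_DD + g0 V_DD / 2) / (w_ld (n_on + n_off) + g0)

A rigidly translating object generates equal ON (trailing edge) and OFF
(leading edge) counts that cancel exactly, leaving the node at mid-rail.
An approaching (looming) object has only leading edges: a dark loom
yields pure OFF activity that pulls the node low, a bright loom pure ON
activity that pulls it high.  An ideal band detector around ``V_DD / 2``
emits a spike only when the node deviates past a skewed-buffer threshold
(``V_TH,UP`` about 600 mV at 0.8 V supply; the low trip mirrors it about
mid-rail by default).

This is the 2-D generalization of a 1-D pair-array: the cancellation
logic depends only on ON/OFF counts, which the 2-D sum preserves, and
the 1-D case is recovered on one-pixel-tall fields.  LD pools *all*
pixels of a field territory — no center/surround split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BipolarMap, EventStream, latch_events
from .feature_oms import SPIKE_COLUMNS
from .receptive_field import RFMap

__all__ = ["LDParams", "ld_vint", "ld_spike", "ld_pipeline", "min_off_count_for_spike"]


@dataclass
class LDParams:
    """Electrical parameters of the LD pair array and band logic."""

    vdd: float = 0.8
    g0: float = 1.0
    w_ld: float = 1.0
    v_th_up: float = 0.6
    v_th_dn: float | None = None

    def __post_init__(self) -> None:
        if not self.vdd > 0:
            raise ValueError("vdd must be positive")
        if not self.g0 > 0:
            raise ValueError("g0 must be positive")
        if self.v_th_dn is None:
            self.v_th_dn = self.vdd - self.v_th_up
        if not self.v_th_dn < self.vdd / 2 < self.v_th_up:
            raise ValueError(
                "band thresholds must straddle mid-rail: "
                f"v_th_dn={self.v_th_dn} < vdd/2={self.vdd / 2} < "
                f"v_th_up={self.v_th_up} violated"
            )


def ld_vint(n_on, n_off, p: LDParams):
    """Steady-state node voltage of the ON/OFF pair-array divider."""
    g_up = p.w_ld * np.asarray(n_on, dtype=float)
    g_dn = p.w_ld * np.asarray(n_off, dtype=float)
    return (g_up * p.vdd + p.g0 * p.vdd / 2.0) / (g_up + g_dn + p.g0)


def ld_spike(v_int, p: LDParams) -> np.ndarray:
    """Band decision: 'high' above ``v_th_up``, 'low' below ``v_th_dn``.

    Returns an object array of {'high', 'low', 'none'} matching the
    input shape (a plain string for scalar input).
    """
    v = np.asarray(v_int, dtype=float)
    out = np.full(v.shape, "none", dtype=object)
    out[v > p.v_th_up] = "high"
    out[v < p.v_th_dn] = "low"
    if out.ndim == 0:
        return out[()]
    return out


def min_off_count_for_spike(p: LDParams) -> int:
    """Smallest pure-OFF activation count that trips the low side.

    From ``ld_vint(0, n) < v_th_dn``:
    ``n > g0 (vdd/2 - v_th_dn) / (w_ld v_th_dn)``.
    """
    bound = p.g0 * (p.vdd / 2.0 - p.v_th_dn) / (p.w_ld * p.v_th_dn)
    return int(np.floor(bound)) + 1


def ld_pipeline(
    bipolar: BipolarMap | EventStream,
    rf: RFMap,
    p: LDParams | None = None,
) -> pd.DataFrame:
    """Evaluate the LD circuit per field territory for every transition.

    ``n_on`` / ``n_off`` count pixels of the field's full territory with
    ON / OFF signals in the transition (events are latched per frame
    period).  Output schema matches the OMS pipeline, with
    ``feature == "LD"`` and ``side`` reporting bright ('high') vs dark
    ('low') looming.
    """
    p = p or LDParams()
    if isinstance(bipolar, EventStream):
        if bipolar.shape != (rf.height, rf.width):
            raise ValueError(
                f"event geometry {bipolar.shape} does not match the "
                f"RFMap geometry {(rf.height, rf.width)}"
            )
        t_max = bipolar.t_us.max() if len(bipolar) else 0.0
        k = max(1, int(np.ceil(t_max / bipolar.frame_period_us)))
        on, off = latch_events(bipolar, k)
    else:
        if bipolar.shape != (rf.height, rf.width):
            raise ValueError(
                f"bipolar geometry {bipolar.shape} does not match the "
                f"RFMap geometry {(rf.height, rf.width)}"
            )
        on = bipolar.data > 0
        off = bipolar.data < 0
        k = bipolar.n_transitions
    on_flat = on.reshape(k, -1)
    off_flat = off.reshape(k, -1)
    rows = []
    for f in rf.field_ids:
        terr = rf.territories[f]
        n_on = on_flat[:, terr].sum(axis=1)
        n_off = off_flat[:, terr].sum(axis=1)
        v = ld_vint(n_on, n_off, p)
        side = ld_spike(v, p)
        for t in range(k):
            rows.append((t + 1, f[0], f[1], "LD", side[t], v[t]))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    return df.sort_values(["t", "field_row", "field_col"], ignore_index=True)
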