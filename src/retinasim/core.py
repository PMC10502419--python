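"""Core data containers shared across the simulator stages.

Conventions (used everywhere in the package):

* coordinates are 0-based ``(row, col)``, origin at the top-left;
* frame indices are 0-based; *transition* ``k`` compares frames ``k-1 -> k``,
  so a stack of ``T`` frames has ``T - 1`` transitions indexed ``1 .. T-1``;
* an ON signal means the light intensity *increased*, OFF that it decreased;
* intensities are unitless photocurrent proxies, always ``>= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameStack", "BipolarMap", "EventStream", "latch_events"]


@dataclass
class FrameStack:
    """A ``T x H x W`` stack of nonnegative intensity frames.

    Parameters
    ----------
    frames : ndarray
        Nonnegative intensities (photocurrent proxies), shape ``(T, H, W)``.
    frame_period_us : float
        Time between consecutive frames, microseconds. Must be positive.
    meta : dict
        Free-form provenance tags (scenario name, generator parameters, ...).
    """

    frames: np.ndarray
    frame_period_us: float = 1000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a T x H x W array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("frame stack must contain at least one frame")
        if not np.all(self.frames >= 0):
            raise ValueError("intensities must be nonnegative")
        if not self.frame_period_us > 0:
            raise ValueError("frame_period_us must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(H, W)``."""
        return self.frames.shape[1:]

    def frame_time_us(self, index: int) -> float:
        """Timestamp of frame ``index`` (frame 0 is at t = 0)."""
        return index * self.frame_period_us


@dataclass
class BipolarMap:
    """Per-transition ternary ON/OFF/none maps (the synchronous APS path).

    ``data[k - 1]`` holds the map for transition ``k`` (frames ``k-1 -> k``)
    with values ``+1`` (ON), ``-1`` (OFF) and ``0`` (none).  The first frame
    has no map because change detection needs a predecessor frame.
    """

    data: np.ndarray
    frame_period_us: float = 1000.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 3:
            raise ValueError(
                f"bipolar data must be (T-1) x H x W, got shape {self.data.shape}"
            )
        bad = np.setdiff1d(np.unique(self.data), [-1, 0, 1])
        if bad.size:
            raise ValueError(f"bipolar values must be in {{-1, 0, 1}}, found {bad}")

    @property
    def n_transitions(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def activity(self) -> np.ndarray:
        """Boolean map of pixels with *any* bipolar signal (ON or OFF)."""
        return self.data != 0


@dataclass
class EventStream:
    """Timestamped ON/OFF events (the asynchronous DVS path).

    Events are sorted by timestamp, ties broken in raster order ``(y, x)``.
    Polarity is ``+1`` for ON (intensity up) and ``-1`` for OFF.
    """

    t_us: np.ndarray
    x: np.ndarray
    y: np.ndarray
    polarity: np.ndarray
    shape: tuple[int, int] = (0, 0)
    frame_period_us: float = 1000.0

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=float)
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        self.polarity = np.asarray(self.polarity, dtype=np.int8)
        n = self.t_us.size
        if not (self.x.size == self.y.size == self.polarity.size == n):
            raise ValueError("event arrays must have equal length")
        if n and np.any(np.diff(self.t_us) < 0):
            raise ValueError("event timestamps must be non-decreasing")
        if n and self.shape != (0, 0):
            h, w = self.shape
            if (
                self.x.min() < 0
                or self.y.min() < 0
                or self.x.max() >= w
                or self.y.max() >= h
            ):
                raise ValueError("event coordinates fall outside the frame bounds")
        bad = np.setdiff1d(np.unique(self.polarity), [-1, 1])
        if bad.size:
            raise ValueError("polarity must be +1 or -1")

    def __len__(self) -> int:
        return self.t_us.size


def latch_events(
    events: EventStream, n_transitions: int
) -> tuple[np.ndarray, np.ndarray]:
    """Latch an event stream into per-frame-period ON/OFF presence maps.

    Feature circuits evaluate once per frame period even for asynchronous
    input: window ``k`` (k = 1..n_transitions) collects events with
    ``t in ((k-1) * T, k * T]``; a pixel with at least one latched event of a
    polarity counts once for that polarity.

    Returns
    -------
    on, off : ndarray of bool, shape ``(n_transitions, H, W)``
    """
    h, w = events.shape
    if h == 0 or w == 0:
        raise ValueError("event stream carries no spatial shape")
    on = np.zeros((n_transitions, h, w), dtype=bool)
    off = np.zeros((n_transitions, h, w), dtype=bool)
    if len(events) == 0:
        return on, off
    period = events.frame_period_us
    win = np.ceil(events.t_us / period).astype(int)
    win = np.clip(win, 1, n_transitions) - 1
    pos = events.polarity > 0
    on[win[pos], events.y[pos], events.x[pos]] = True
    neg = ~pos
    off[win[neg], events.y[neg], events.x[neg]] = True
    return on, off
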