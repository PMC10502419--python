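"""Deterministic, seeded generators for the simulator's test scenes.

The scenes emulate the classic probes for the two retinal feature circuits:

* **object-motion sensitivity (OMS)** — a textured background under rigid
  global translation (emulating self-motion), with an object that is either
  fixed or moving differentially;
* **looming detection (LD)** — a bright or dark square on a uniform
  background that either approaches (grows) or translates rigidly.

Motion is integer-pixel with periodic wrap-around, so global background
motion is a pure permutation of pixel values: the event statistics it
induces are stationary, which is what makes the OMS balance property
exactly testable.  Sub-pixel motion is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import FrameStack

__all__ = ["SceneSpec", "make_background", "composite_object", "scenario", "SCENARIOS"]

_TEXTURES = ("random", "checker", "lines")
_SHAPES = ("square", "disc")
_MOTIONS = ("fixed", "translate", "loom")

#: Default multiplicative contrast of the object against the local
#: background mean.  Chosen well past the 30 % bipolar threshold so object
#: edges always saturate the change detector.
OBJECT_CONTRAST = {"dark": 0.3, "bright": 3.0}


@dataclass
class SceneSpec:
    """Full description of one synthetic scene.

    Background
    ----------
    texture : {"random", "checker", "lines"}
        ``random`` draws iid gray levels ``base * (1 + contrast * U(-1, 1))``;
        ``checker`` is a full checkerboard at ``base * (1 +/- contrast)``;
        ``lines`` marks every ``texture_period``-th row as a high-contrast
        checker line and leaves other rows at the uniform base level, giving
        a spatially uniform event rate under horizontal global motion.
    bg_velocity : (int, int)
        Rigid background translation per frame, ``(d_row, d_col)`` pixels.

    Object
    ------
    object_shape : {"square", "disc"} or None
        ``None`` means background only.  Sizes are half-widths: a square of
        half-width ``h`` spans ``2 h + 1`` pixels per side.
    object_motion : {"fixed", "translate", "loom"}
        ``loom`` grows the half-width by ``growth_rate`` px/frame about a
        fixed centroid.
    """

    height: int = 63
    width: int = 63
    n_frames: int = 20
    seed: int = 0
    frame_period_us: float = 1000.0
    # background
    texture: str = "lines"
    base_intensity: float = 0.5
    texture_contrast: float = 0.3
    texture_period: int = 3
    bg_velocity: tuple[int, int] = (0, 0)
    # object (optional)
    object_shape: str | None = None
    object_polarity: str = "dark"
    object_center: tuple[int, int] = (31, 31)
    object_half_width: int = 5
    object_motion: str = "fixed"
    object_velocity: tuple[int, int] = (0, 0)
    growth_rate: int = 1
    object_contrast: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.texture not in _TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}; one of {_TEXTURES}")
        if self.object_shape is not None and self.object_shape not in _SHAPES:
            raise ValueError(f"unknown object shape {self.object_shape!r}")
        if self.object_motion not in _MOTIONS:
            raise ValueError(f"unknown object motion {self.object_motion!r}")
        if self.object_polarity not in OBJECT_CONTRAST:
            raise ValueError("object_polarity must be 'dark' or 'bright'")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.object_motion == "loom" and not self.growth_rate > 0:
            raise ValueError("growth rate must be > 0 for loom")
        for v in (*self.bg_velocity, *self.object_velocity):
            if not float(v).is_integer():
                raise ValueError(
                    "sub-pixel motion is not supported: velocity components "
                    f"must be integers, got {v!r}"
                )


def _texture_frame(spec: SceneSpec) -> np.ndarray:
    """Frame 0 of the background texture (seeded, bit-reproducible)."""
    h, w, b, c = spec.height, spec.width, spec.base_intensity, spec.texture_contrast
    rows, cols = np.ogrid[:h, :w]
    if spec.texture == "random":
        rng = np.random.default_rng(spec.seed)
        return b * (1.0 + c * rng.uniform(-1.0, 1.0, size=(h, w)))
    checker = np.where((rows + cols) % 2 == 0, b * (1.0 + c), b * (1.0 - c))
    if spec.texture == "checker":
        return np.broadcast_to(checker, (h, w)).copy()
    # "lines": only every texture_period-th row carries the checker contrast
    active = rows % spec.texture_period == 0
    return np.where(active, checker, b)


def make_background(spec: SceneSpec) -> FrameStack:
    """Generate a background-only stack under rigid wrap-around translation.

    Frame ``t`` equals frame 0 translated by ``t * bg_velocity`` with
    periodic wrap, so the multiset of pixel values is frame-invariant.
    """
    frame0 = _texture_frame(spec)
    dr, dc = (int(v) for v in spec.bg_velocity)
    frames = np.stack(
        [np.roll(frame0, (t * dr, t * dc), axis=(0, 1)) for t in range(spec.n_frames)]
    )
    meta = {
        "generator": "make_background",
        "texture": spec.texture,
        "bg_velocity": (dr, dc),
        "seed": spec.seed,
        **spec.meta,
    }
    return FrameStack(frames, spec.frame_period_us, meta)


def object_masks(spec: SceneSpec) -> np.ndarray:
    """Ground-truth object footprint per frame, shape ``(T, H, W)`` bool.

    Raises if the object leaves the canvas, naming the first offending frame.
    """
    if spec.object_shape is None:
        return np.zeros((spec.n_frames, spec.height, spec.width), dtype=bool)
    rows, cols = np.ogrid[: spec.height, : spec.width]
    masks = np.empty((spec.n_frames, spec.height, spec.width), dtype=bool)
    r0, c0 = spec.object_center
    vr, vc = (int(v) for v in spec.object_velocity)
    for t in range(spec.n_frames):
        h = spec.object_half_width
        r, c = r0, c0
        if spec.object_motion == "translate":
            r, c = r0 + t * vr, c0 + t * vc
        elif spec.object_motion == "loom":
            h = spec.object_half_width + t * spec.growth_rate
        if r - h < 0 or c - h < 0 or r + h >= spec.height or c + h >= spec.width:
            raise ValueError(
                f"object exits the canvas at frame {t}: extent "
                f"[{r - h}, {r + h}] x [{c - h}, {c + h}] vs "
                f"{spec.height} x {spec.width}"
            )
        if spec.object_shape == "square":
            masks[t] = (np.abs(rows - r) <= h) & (np.abs(cols - c) <= h)
        else:  # disc
            masks[t] = (rows - r) ** 2 + (cols - c) ** 2 <= h * h
    return masks


def composite_object(bg: FrameStack, spec: SceneSpec) -> tuple[FrameStack, np.ndarray]:
    """Overwrite the background with the scene's object, frame by frame.

    The object is rendered at a constant intensity equal to the configured
    multiplicative contrast times the mean background intensity under its
    initial footprint (dark = x0.3, bright = x3 by default), so its edges
    always exceed the 30 % bipolar threshold.

    Returns the composited stack together with the per-frame ground-truth
    masks.
    """
    if spec.object_shape is None:
        return bg, object_masks(spec)
    if bg.frames.shape != (spec.n_frames, spec.height, spec.width):
        raise ValueError("background stack does not match the scene spec geometry")
    masks = object_masks(spec)
    factor = (
        spec.object_contrast
        if spec.object_contrast is not None
        else OBJECT_CONTRAST[spec.object_polarity]
    )
    level = factor * float(bg.frames[0][masks[0]].mean())
    frames = bg.frames.copy()
    for t in range(spec.n_frames):
        frames[t][masks[t]] = level
    meta = dict(bg.meta)
    meta.update(
        generator="composite_object",
        object_shape=spec.object_shape,
        object_polarity=spec.object_polarity,
        object_motion=spec.object_motion,
        object_intensity=level,
    )
    return FrameStack(frames, bg.frame_period_us, meta), masks


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------

def _scenario_specs(seed: int, size: tuple[int, int], n_frames: int | None):
    h, w = size
    cr, cc = h // 2, w // 2
    base = dict(height=h, width=w, seed=seed)
    return {
        # Textured background translating 1 px/frame with a *fixed* dark
        # object: every field sees the same balanced event rate, no
        # differential motion anywhere.
        "oms_global_only": SceneSpec(
            **base,
            n_frames=n_frames or 20,
            texture="lines",
            bg_velocity=(0, 1),
            object_shape="square",
            object_polarity="dark",
            object_center=(cr, cc),
            object_half_width=5,
            object_motion="fixed",
        ),
        # Same translating background plus an object moving diagonally at
        # 3 px/frame: differential motion confined to the fields it crosses.
        "oms_global_plus_object": SceneSpec(
            **base,
            n_frames=n_frames or 14,
            texture="lines",
            bg_velocity=(0, 1),
            object_shape="square",
            object_polarity="bright",
            object_center=(h // 5, w // 5),
            object_half_width=5,
            object_motion="translate",
            object_velocity=(3, 3),
        ),
        # Bright square growing 1 px half-width per frame on a static
        # uniform background: every changed pixel is an ON leading edge.
        "ld_loom_bright": SceneSpec(
            **base,
            n_frames=n_frames or 8,
            texture="checker",
            texture_contrast=0.0,
            bg_velocity=(0, 0),
            object_shape="square",
            object_polarity="bright",
            object_center=(cr, cc),
            object_half_width=2,
            object_motion="loom",
            growth_rate=1,
        ),
        "ld_loom_dark": SceneSpec(
            **base,
            n_frames=n_frames or 8,
            texture="checker",
            texture_contrast=0.0,
            bg_velocity=(0, 0),
            object_shape="square",
            object_polarity="dark",
            object_center=(cr, cc),
            object_half_width=2,
            object_motion="loom",
            growth_rate=1,
        ),
        # Rigid horizontal translation: leading-edge and trailing-edge
        # column counts are equal by construction, so ON/OFF cancel.
        "ld_translate": SceneSpec(
            **base,
            n_frames=n_frames or 8,
            texture="checker",
            texture_contrast=0.0,
            bg_velocity=(0, 0),
            object_shape="square",
            object_polarity="dark",
            object_center=(cr, max(3 + 3, cc - 7)),
            object_half_width=3,
            object_motion="translate",
            object_velocity=(0, 2),
        ),
    }


SCENARIOS = tuple(_scenario_specs(0, (63, 63), None))


def scenario(
    name: str,
    seed: int = 0,
    size: tuple[int, int] = (63, 63),
    n_frames: int | None = None,
) -> tuple[FrameStack, dict]:
    """Build a canonical named test scene.

    Returns
    -------
    stack : FrameStack
        The rendered scene; generation parameters are recorded in ``meta``.
    truth : dict
        Ground truth: ``masks`` (T x H x W object footprints), ``spec``
        (the full :class:`SceneSpec`), ``object_area`` per frame and the
        background velocity.
    """
    specs = _scenario_specs(seed, size, n_frames)
    if name not in specs:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(specs)}"
        )
    spec = replace(specs[name], meta={"scenario": name})
    bg = make_background(spec)
    stack, masks = composite_object(bg, spec)
    truth = {
        "spec": spec,
        "masks": masks,
        "object_area": masks.reshape(spec.n_frames, -1).sum(axis=1),
        "bg_velocity": spec.bg_velocity,
    }
    return stack, truth
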