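"""Readers, writers, configuration and the end-to-end pipeline.

File formats
------------
* frames: NPZ (``frames`` array, ``frame_period_us`` scalar) or a
  directory of grayscale PNG/TIFF frames sorted lexicographically
  (16-bit PNG on write); masks ride along under the NPZ key ``masks``;
* bipolar maps: NPZ int8 ``(T-1) x H x W`` with values {+1, -1, 0};
* event streams and spike tables: CSV with a versioned ``#`` schema
  comment line;
* receptive-field maps: JSON; configuration: YAML (JSON is valid YAML).

All randomness flows from ``Config.seed``: two runs with equal configs
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import BipolarMap, EventStream, FrameStack
from .feature_ld import LDParams, ld_pipeline
from .feature_oms import AnalogParams, oms_pipeline
from .phototransduction import (
    PixelParams,
    detect_bipolar_aps,
    detect_bipolar_ideal,
    dvs_events,
)
from .receptive_field import RFMap, build_rfmap
from .stimuli import scenario as make_scenario
from .variation import MCResult, MCSpec

logger = logging.getLogger("retinasim")

__all__ = [
    "read_frames",
    "write_frames",
    "read_bipolar",
    "write_bipolar",
    "read_events_csv",
    "write_events_csv",
    "read_spikes_csv",
    "write_spikes_csv",
    "write_mc_result",
    "Config",
    "run_pipeline",
]

_EVENT_SCHEMA = "# retinasim events v1"
_SPIKE_SCHEMA = "# retinasim spikes v1"

#: Rec. 709 luma weights used to collapse RGB input to luminance.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

def read_frames(path: str | Path) -> FrameStack:
    """Load a frame stack from NPZ, an image directory, or a video file.

    Intensities come back as nonnegative floats; 16-bit inputs keep their
    native [0, 65535] scale.  RGB frames are collapsed to luminance with
    Rec. 709 weights (a warning is logged).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir()
            if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in directory {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len({s[:2] for s in shapes}) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        frames = np.stack([_to_gray(f) for f in frames])
        return FrameStack(frames, meta={"source": str(path), "format": "dir"})
    if path.suffix == ".npz":
        with np.load(path) as z:
            frames = z["frames"]
            period = float(z["frame_period_us"]) if "frame_period_us" in z else 1000.0
        return FrameStack(frames, period, meta={"source": str(path), "format": "npz"})
    # optional video decode
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - decoder availability varies
        raise ValueError(f"cannot decode frames from {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):
        raw = raw[None]
    frames = np.stack([_to_gray(f) for f in raw])
    return FrameStack(frames, meta={"source": str(path), "format": "video"})


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        logger.warning("RGB input collapsed to luminance (Rec. 709 weights)")
        return frame[..., :3].astype(float) @ _LUMA
    return frame.astype(float)


def write_frames(
    stack: FrameStack, path: str | Path, masks: np.ndarray | None = None
) -> Path:
    """Write a frame stack as NPZ, or as 16-bit grayscale PNGs to a directory."""
    path = Path(path)
    if path.suffix == ".npz":
        payload = {
            "frames": stack.frames,
            "frame_period_us": np.float64(stack.frame_period_us),
        }
        if masks is not None:
            payload["masks"] = masks.astype(np.uint8)
        np.savez(path, **payload)
        return path
    path.mkdir(parents=True, exist_ok=True)
    peak = stack.frames.max()
    scale = 65535.0 / peak if peak > 0 else 1.0
    for t in range(stack.n_frames):
        img = np.round(stack.frames[t] * scale).astype(np.uint16)
        iio.imwrite(path / f"frame_{t:05d}.png", img)
    return path


# ---------------------------------------------------------------------------
# Bipolar maps, events, spikes
# ---------------------------------------------------------------------------

def write_bipolar(bipolar: BipolarMap, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        bipolar=bipolar.data,
        frame_period_us=np.float64(bipolar.frame_period_us),
    )
    return path


def read_bipolar(path: str | Path) -> BipolarMap:
    with np.load(path) as z:
        return BipolarMap(z["bipolar"], float(z["frame_period_us"]))


def write_events_csv(events: EventStream, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_us": events.t_us,
            "x": events.x,
            "y": events.y,
            "polarity": events.polarity,
        }
    )
    with open(path, "w") as fh:
        fh.write(_EVENT_SCHEMA + "\n")
        df.to_csv(fh, index=False)
    return path


def read_events_csv(
    path: str | Path, shape: tuple[int, int] = (0, 0), frame_period_us: float = 1000.0
) -> EventStream:
    df = pd.read_csv(path, comment="#")
    return EventStream(
        df["t_us"].to_numpy(),
        df["x"].to_numpy(),
        df["y"].to_numpy(),
        df["polarity"].to_numpy(),
        shape=shape,
        frame_period_us=frame_period_us,
    )


def write_spikes_csv(spikes: pd.DataFrame, path: str | Path) -> Path:
    """Write a spike table (``v_int`` converted to millivolts)."""
    path = Path(path)
    out = spikes.copy()
    out["v_int_mV"] = out.pop("v_int") * 1e3
    with open(path, "w") as fh:
        fh.write(_SPIKE_SCHEMA + "\n")
        out.to_csv(fh, index=False)
    return path


def read_spikes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["v_int"] = df.pop("v_int_mV") / 1e3
    return df


def write_mc_result(result: MCResult, out_dir: str | Path) -> Path:
    """Write per-sample rows (CSV) and the summary (JSON) of an MC run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.samples.to_csv(out_dir / f"mc_{result.stage}_samples.csv", index=False)
    payload = {
        "stage": result.stage,
        "spec": dataclasses.asdict(result.spec),
        "summary": result.summary,
        "version": __version__,
    }
    with open(out_dir / f"mc_{result.stage}_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return out_dir


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """End-to-end pipeline configuration.

    Sections mirror the stage parameter dataclasses; unknown keys are
    rejected so typos cannot silently fall back to defaults.
    """

    seed: int = 0
    scenario: str | None = "oms_global_only"
    input_path: str | None = None
    size: tuple[int, int] = (63, 63)
    n_frames: int | None = None
    backend: str = "ideal"
    features: tuple[str, ...] = ("oms", "ld")
    grid: tuple[int, int] = (3, 3)
    donor_fraction: float = 0.25
    pixel: PixelParams = field(default_factory=PixelParams)
    oms: AnalogParams = field(default_factory=AnalogParams)
    ld: LDParams = field(default_factory=LDParams)
    mc: MCSpec = field(default_factory=MCSpec)

    def __post_init__(self) -> None:
        if self.backend not in ("ideal", "aps", "dvs"):
            raise ValueError("backend must be 'ideal', 'aps' or 'dvs'")
        unknown = set(self.features) - {"oms", "ld"}
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if self.scenario is None and self.input_path is None:
            raise ValueError("config needs either a scenario or an input_path")

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        data = dict(data)
        sections = {
            "pixel": PixelParams,
            "oms": AnalogParams,
            "ld": LDParams,
            "mc": MCSpec,
        }
        kwargs = {}
        for name, klass in sections.items():
            if name in data:
                sub = data.pop(name)
                _check_keys(sub, klass, name)
                kwargs[name] = klass(**sub)
        _check_keys(data, cls, "config")
        for tup in ("size", "grid", "features"):
            if tup in data and data[tup] is not None:
                data[tup] = tuple(data[tup])
        return cls(**data, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for tup in ("size", "grid", "features"):
            out[tup] = list(out[tup])
        return out

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def _check_keys(data: dict, klass, section: str) -> None:
    valid = {f.name for f in dataclasses.fields(klass)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"valid keys: {sorted(valid)}"
        )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: Config, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict]:
    """Execute stimulus/file input -> bipolar backend -> OMS/LD -> spikes.

    Returns the combined spike table and a JSON-serializable report with
    per-field spike counts, per-transition event counts, the effective
    parameters, seed and package version.  If ``out_dir`` is given, the
    spike CSV and report JSON are written there.
    """
    logger.info("pipeline: acquiring frames")
    if config.input_path is not None:
        stack = read_frames(config.input_path)
        truth = None
    else:
        stack, truth = make_scenario(
            config.scenario, seed=config.seed, size=config.size,
            n_frames=config.n_frames,
        )
    h, w = stack.shape

    logger.info("pipeline: bipolar backend %s", config.backend)
    if config.backend == "ideal":
        bipolar = detect_bipolar_ideal(
            stack, config.pixel.theta, config.pixel.eps_dark
        )
    elif config.backend == "aps":
        bipolar = detect_bipolar_aps(stack, config.pixel)
    else:
        bipolar = dvs_events(stack, config.pixel)

    logger.info("pipeline: receptive fields %s", config.grid)
    rf = build_rfmap(
        h, w, *config.grid,
        donor_fraction=config.donor_fraction, w_c=config.oms.w_c,
    )

    tables = []
    if "oms" in config.features:
        logger.info("pipeline: OMS stage")
        tables.append(oms_pipeline(bipolar, rf, config.oms))
    if "ld" in config.features:
        logger.info("pipeline: LD stage")
        tables.append(ld_pipeline(bipolar, rf, config.ld))
    spikes = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["t", "field_row", "field_col", "feature", "side", "v_int"]
    )

    spiking = spikes[spikes["side"] != "none"]
    per_field = {
        f"{feat}:{r},{c}": int(n)
        for (feat, r, c), n in spiking.groupby(
            ["feature", "field_row", "field_col"]
        ).size().items()
    }
    if isinstance(bipolar, BipolarMap):
        events_per_transition = bipolar.activity().sum(axis=(1, 2)).tolist()
    else:
        k = max(1, int(np.ceil(bipolar.t_us.max() / bipolar.frame_period_us))) \
            if len(bipolar) else 0
        counts = np.zeros(k, dtype=int)
        if k:
            win = np.clip(
                np.ceil(bipolar.t_us / bipolar.frame_period_us).astype(int), 1, k
            )
            np.add.at(counts, win - 1, 1)
        events_per_transition = counts.tolist()
    report = {
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "backend": config.backend,
        "n_frames": stack.n_frames,
        "shape": [h, w],
        "spike_counts_per_field": per_field,
        "total_spikes": int(len(spiking)),
        "events_per_transition": [int(n) for n in events_per_transition],
        "config": config.to_dict(),
    }
    if truth is not None:
        report["object_area_per_frame"] = [int(a) for a in truth["object_area"]]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_spikes_csv(spikes, out_dir / "spikes.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("pipeline: wrote %s", out_dir)
    return spikes, report
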