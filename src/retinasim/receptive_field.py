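"""Center-surround receptive-field geometry on a pixel array.

The pixel array is tiled into rectangular *territories*, one per feature
field.  Within each territory a deterministic raster-strided subset of
pixels ("donors") is set aside; in ``fanout`` mode every donor's bipolar
signal is routed to the surround set of each 8-connected neighboring
field.  Donors are excluded from their own field's center, so each
territory donates *fewer* pixels than it keeps while every interior
field's surround outnumbers its center (for donor fractions above 1/9).

Surround devices carry a smaller conductance than center devices;
:func:`balanced_weights` sets ``w_s = w_c |center| / |surround|`` per
field, so equal per-pixel event probability in center and surround gives
equal expected pull-up and pull-down strength on the integration node.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RFMap",
    "tile_centers",
    "assign_surround",
    "balanced_weights",
    "build_rfmap",
]

FieldId = tuple[int, int]


@dataclass
class RFMap:
    """Receptive-field geometry and per-field weights.

    Pixel sets are stored as flat indices (``row * width + col``) for fast
    counting; helpers convert to ``(row, col)`` pairs for serialization.
    """

    height: int
    width: int
    grid_rows: int
    grid_cols: int
    donor_fraction: float
    mode: str
    territories: dict[FieldId, np.ndarray]
    centers: dict[FieldId, np.ndarray]
    donors: dict[FieldId, np.ndarray]
    surrounds: dict[FieldId, np.ndarray]
    w_c: dict[FieldId, float] = field(default_factory=dict)
    w_s: dict[FieldId, float] = field(default_factory=dict)

    @property
    def field_ids(self) -> list[FieldId]:
        """Field ids in raster order."""
        return [
            (i, j) for i in range(self.grid_rows) for j in range(self.grid_cols)
        ]

    def neighbors(self, f: FieldId) -> list[FieldId]:
        """8-connected neighboring fields (no wrap at the array edge)."""
        i, j = f
        out = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < self.grid_rows and 0 <= nj < self.grid_cols:
                    out.append((ni, nj))
        return out

    def to_json(self) -> str:
        def pairs(idx: np.ndarray) -> list[list[int]]:
            return [[int(i) // self.width, int(i) % self.width] for i in idx]

        obj = {
            "height": self.height,
            "width": self.width,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "donor_fraction": self.donor_fraction,
            "mode": self.mode,
            "fields": {
                f"{i},{j}": {
                    "center": pairs(self.centers[(i, j)]),
                    "donors": pairs(self.donors[(i, j)]),
                    "surround": pairs(self.surrounds[(i, j)]),
                    "w_c": self.w_c.get((i, j)),
                    "w_s": self.w_s.get((i, j)),
                }
                for (i, j) in self.field_ids
            },
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "RFMap":
        obj = json.loads(text)
        w = obj["width"]

        def flat(pairs: list[list[int]]) -> np.ndarray:
            return np.asarray([r * w + c for r, c in pairs], dtype=int)

        centers, donors, surrounds, w_c, w_s, terr = {}, {}, {}, {}, {}, {}
        for key, val in obj["fields"].items():
            i, j = (int(s) for s in key.split(","))
            centers[(i, j)] = flat(val["center"])
            donors[(i, j)] = flat(val["donors"])
            surrounds[(i, j)] = flat(val["surround"])
            terr[(i, j)] = np.sort(
                np.concatenate([centers[(i, j)], donors[(i, j)]])
            )
            if val.get("w_c") is not None:
                w_c[(i, j)] = float(val["w_c"])
            if val.get("w_s") is not None:
                w_s[(i, j)] = float(val["w_s"])
        return cls(
            height=obj["height"],
            width=w,
            grid_rows=obj["grid_rows"],
            grid_cols=obj["grid_cols"],
            donor_fraction=obj["donor_fraction"],
            mode=obj["mode"],
            territories=terr,
            centers=centers,
            donors=donors,
            surrounds=surrounds,
            w_c=w_c,
            w_s=w_s,
        )


def tile_centers(
    height: int, width: int, grid_rows: int = 3, grid_cols: int = 3
) -> dict[FieldId, np.ndarray]:
    """Partition an ``H x W`` array into a grid of rectangular territories.

    Territories are returned as flat pixel-index arrays in raster order,
    keyed by ``(grid_row, grid_col)``.  ``H`` and ``W`` must be divisible
    by the grid shape; otherwise the error names the padding required.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid shape must be at least 1 x 1")
    if height % grid_rows or width % grid_cols:
        pad_h = (-height) % grid_rows
        pad_w = (-width) % grid_cols
        raise ValueError(
            f"array shape {height} x {width} is not divisible by the "
            f"{grid_rows} x {grid_cols} grid; pad to "
            f"{height + pad_h} x {width + pad_w}"
        )
    th, tw = height // grid_rows, width // grid_cols
    territories: dict[FieldId, np.ndarray] = {}
    for i in range(grid_rows):
        for j in range(grid_cols):
            rows = np.arange(i * th, (i + 1) * th)
            cols = np.arange(j * tw, (j + 1) * tw)
            territories[(i, j)] = (
                rows[:, None] * width + cols[None, :]
            ).ravel()
    return territories


def assign_surround(
    territories: dict[FieldId, np.ndarray],
    height: int,
    width: int,
    donor_fraction: float = 0.25,
    mode: str = "fanout",
) -> RFMap:
    """Designate donor pixels and route them to neighboring surrounds.

    Within each territory, every ``ceil(1 / donor_fraction)``-th pixel in
    raster order (stride phase 0) becomes a donor.  Donors are excluded
    from their own field's center; in ``fanout`` mode each donor feeds the
    surround set of *every* 8-connected neighboring field — routing is
    pure bookkeeping, one signal may drive several fields.
    """
    if not 0 < donor_fraction < 0.5:
        raise ValueError(
            "interleaved pixels must be fewer than center pixels: "
            f"donor_fraction must lie in (0, 0.5), got {donor_fraction}"
        )
    if mode != "fanout":
        raise ValueError(f"unknown surround assignment mode {mode!r}")
    grid_rows = max(i for i, _ in territories) + 1
    grid_cols = max(j for _, j in territories) + 1
    stride = math.ceil(1.0 / donor_fraction)
    centers, donors = {}, {}
    for f, terr in territories.items():
        terr = np.sort(np.asarray(terr, dtype=int))
        donors[f] = terr[::stride]
        mask = np.ones(terr.size, dtype=bool)
        mask[::stride] = False
        centers[f] = terr[mask]
    rf = RFMap(
        height=height,
        width=width,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        donor_fraction=donor_fraction,
        mode=mode,
        territories={f: np.sort(np.asarray(t, int)) for f, t in territories.items()},
        centers=centers,
        donors=donors,
        surrounds={},
    )
    for f in rf.field_ids:
        neigh = rf.neighbors(f)
        if neigh:
            rf.surrounds[f] = np.concatenate([donors[n] for n in neigh])
        else:
            rf.surrounds[f] = np.empty(0, dtype=int)
    return rf


def balanced_weights(rf: RFMap, w_c: float = 1.0) -> RFMap:
    """Set surround weights so area imbalance cancels in expectation.

    Per field, ``w_s = w_c * |center| / |surround|``: with equal per-pixel
    event probability in center and surround, expected pull-up and
    pull-down strengths on the integration node are then equal, and
    ``w_s < w_c`` whenever the surround outnumbers the center.
    """
    for f in rf.field_ids:
        if rf.surrounds[f].size == 0:
            raise ValueError(
                f"field {f} has an empty surround (grid too small to "
                "donate pixels); use a grid with at least 2 fields"
            )
        rf.w_c[f] = float(w_c)
        rf.w_s[f] = float(w_c) * rf.centers[f].size / rf.surrounds[f].size
    return rf


def build_rfmap(
    height: int,
    width: int,
    grid_rows: int = 3,
    grid_cols: int = 3,
    donor_fraction: float = 0.25,
    w_c: float = 1.0,
) -> RFMap:
    """Convenience: tile, assign surrounds and balance weights in one call."""
    terr = tile_centers(height, width, grid_rows, grid_cols)
    rf = assign_surround(terr, height, width, donor_fraction)
    return balanced_weights(rf, w_c)
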