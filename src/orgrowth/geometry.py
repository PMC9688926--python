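"""Acquisition geometry of a tiled, z-stacked time-lapse recording.

A recording is laid out as a grid of camera tiles (adjacent tiles share a
fixed overlap fraction), each acquired as a focal stack of ``z_planes``
planes, repeated for ``n_frames`` time points at ``interval_h`` hours.
All physical quantities are in micrometres / hours; image axes follow the
(y down, x right) convention with 0-based pixel indices, and physical
positions are ``pixel_index * pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Layout of one time-lapse recording.

    Defaults mirror a typical organoid culture recording: 2x2 tiles with 15%
    overlap acquired in a meander (serpentine) scan, 10 z-planes spaced
    65 um apart, square 1.29 um pixels, and 97 half-hour frames spanning
    48 h (0 h counts as frame 1).
    """

    tile_rows: int = 2
    tile_cols: int = 2
    overlap_fraction: float = 0.15
    scan_mode: str = "meander"
    z_planes: int = 10
    z_spacing_um: float = 65.0
    pixel_size_um: float = 1.29
    n_frames: int = 97
    interval_h: float = 0.5
    tile_shape_px: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile grid must be at least 1x1")
        if not (0.0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must lie in [0, 0.5)")
        if self.scan_mode not in ("meander", "row_major"):
            raise ValueError(f"unknown scan_mode {self.scan_mode!r}")
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.interval_h <= 0:
            raise ValueError("interval_h must be positive")
        h, w = self.tile_shape_px
        if h < 1 or w < 1:
            raise ValueError("tile_shape_px must be positive")
        object.__setattr__(self, "tile_shape_px", (int(h), int(w)))

    # -- derived layout ----------------------------------------------------

    @property
    def tile_step_px(self) -> tuple[int, int]:
        """Nominal grid pitch (dy, dx) between adjacent tiles, in pixels.

        The pitch is ``tile_extent * (1 - overlap)`` rounded to whole pixels;
        the simulator places tiles on exactly this integer grid.
        """
        h, w = self.tile_shape_px
        return (
            int(round(h * (1.0 - self.overlap_fraction))),
            int(round(w * (1.0 - self.overlap_fraction))),
        )

    @property
    def overlap_px(self) -> tuple[int, int]:
        h, w = self.tile_shape_px
        sy, sx = self.tile_step_px
        return (h - sy, w - sx)

    @property
    def mosaic_shape_px(self) -> tuple[int, int]:
        """Extent of the stitched mosaic at nominal offsets."""
        h, w = self.tile_shape_px
        sy, sx = self.tile_step_px
        return (h + (self.tile_rows - 1) * sy, w + (self.tile_cols - 1) * sx)

    @property
    def n_tiles(self) -> int:
        return self.tile_rows * self.tile_cols

    @property
    def duration_h(self) -> float:
        return (self.n_frames - 1) * self.interval_h

    def nominal_offset(self, row: int, col: int) -> tuple[int, int]:
        """Nominal top-left (dy, dx) of tile (row, col) in the mosaic."""
        sy, sx = self.tile_step_px
        return (row * sy, col * sx)

    def frame_times_h(self):
        import numpy as np

        return np.arange(self.n_frames) * self.interval_h

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tile_shape_px"] = list(self.tile_shape_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        d = dict(d)
        d["tile_shape_px"] = tuple(d["tile_shape_px"])
        return cls(**d)

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load_json(cls, path) -> "AcquisitionGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kw) -> "AcquisitionGeometry":
        return replace(self, **kw)
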