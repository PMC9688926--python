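"""Dimensionality reduction of raw recordings: z-projection and stitching.

Raw stacks (tile x z x frame) are reduced to one stitched 2D mosaic per time
point: each tile's focal stack is collapsed by average-intensity projection
(max available as an option), and the projected tiles are placed on the
nominal overlap grid, optionally refined by normalized cross-correlation of
the shared overlap strips, then blended with linear feathering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry

log = logging.getLogger(__name__)


@dataclass
class ProjectedTile:
    """One z-projected tile of one frame."""

    tile_index: int
    frame: int
    image: np.ndarray
    grid_position: tuple[int, int]


@dataclass
class MosaicFrame:
    """A stitched frame and the per-tile offsets used to build it."""

    frame: int
    image: np.ndarray
    offsets: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)


def z_project(stack: np.ndarray, method: str = "average") -> np.ndarray:
    """Collapse a (z, y, x) focal stack to a single 2D image.

    ``average`` accumulates in float64 and restores the input dtype
    (rounding for integer types); ``max`` takes the per-pixel maximum.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    if method == "average":
        out = stack.mean(axis=0, dtype=np.float64)
        if np.issubdtype(stack.dtype, np.integer):
            info = np.iinfo(stack.dtype)
            out = np.clip(np.rint(out), info.min, info.max)
        return out.astype(stack.dtype)
    if method == "max":
        return stack.max(axis=0)
    raise ValueError(f"unknown projection method {method!r}")


def meander_order(rows: int, cols: int) -> list[tuple[int, int]]:
    """Serpentine acquisition order: even rows left-to-right, odd reversed."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    order = []
    for r in range(rows):
        cs = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        order.extend((r, c) for c in cs)
    return order


def grid_order(rows: int, cols: int, scan_mode: str) -> list[tuple[int, int]]:
    """Grid positions in acquisition order for the given scan mode."""
    if scan_mode == "meander":
        return meander_order(rows, cols)
    if scan_mode == "row_major":
        return [(r, c) for r in range(rows) for c in range(cols)]
    raise ValueError(f"unknown scan_mode {scan_mode!r}")


def project_tiles(
    stack: np.ndarray, geometry: AcquisitionGeometry, frame: int, method: str = "average"
) -> list[ProjectedTile]:
    """Project all tiles of one frame from a (tile, z, frame, y, x) stack."""
    tiles = []
    positions = [
        (r, c) for r in range(geometry.tile_rows) for c in range(geometry.tile_cols)
    ]
    for ti, pos in enumerate(positions):
        tiles.append(
            ProjectedTile(ti, frame, z_project(stack[ti, :, frame], method), pos)
        )
    return tiles


# ---------------------------------------------------------------------------
# stitching


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape patches; nan when degenerate."""
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float((a @ b) / denom)


def _refine_pair(
    ref: np.ndarray,
    mov: np.ndarray,
    nominal_shift: tuple[int, int],
    overlap_px: tuple[int, int],
    axis: int,
) -> tuple[int, int] | None:
    """Best integer shift of ``mov`` relative to ``ref`` near the nominal one.

    ``axis`` is 0 for a vertical neighbor pair (mov below ref), 1 for a
    horizontal pair. Searches +-overlap/2 around the nominal shift by NCC of
    the shared strip; returns None when the correlation is degenerate.
    """
    h, w = ref.shape
    ov = max(overlap_px[axis], 1)
    bound = max(ov // 2, 1)
    best = (float("-inf"), 0, (0, 0))
    found = False
    for dy in range(-bound, bound + 1):
        for dx in range(-bound, bound + 1):
            sy = nominal_shift[0] + dy
            sx = nominal_shift[1] + dx
            # overlap window in ref coordinates
            y0, y1 = max(0, sy), min(h, sy + h)
            x0, x1 = max(0, sx), min(w, sx + w)
            if y1 - y0 < 2 or x1 - x0 < 2:
                continue
            r = ref[y0:y1, x0:x1]
            m = mov[y0 - sy : y1 - sy, x0 - sx : x1 - sx]
            c = _ncc(r, m)
            if np.isnan(c):
                continue
            found = True
            key = (c, -(abs(dy) + abs(dx)))
            if key > (best[0], best[1]):
                best = (c, -(abs(dy) + abs(dx)), (sy, sx))
    if not found:
        return None
    return best[2]


def stitch(
    tiles: list[ProjectedTile],
    geometry: AcquisitionGeometry,
    refine: bool = False,
    offsets: dict[tuple[int, int], tuple[int, int]] | None = None,
) -> MosaicFrame:
    """Stitch one frame's projected tiles into a mosaic.

    Without refinement (or with precomputed ``offsets``) tiles sit at their
    nominal grid offsets. With ``refine`` each tile's offset is adjusted by
    the translation maximizing normalized cross-correlation of the overlap
    strip with its already-placed left (or top) neighbor, bounded by half the
    overlap; degenerate correlation falls back to the nominal offset with a
    logged warning. Overlapping pixels are blended by linear feathering.
    """
    if len(tiles) != geometry.n_tiles:
        raise ValueError(
            f"expected {geometry.n_tiles} tiles, got {len(tiles)}"
        )
    frames = {t.frame for t in tiles}
    if len(frames) != 1:
        raise ValueError("all tiles must belong to the same frame")
    frame = frames.pop()
    th, tw = geometry.tile_shape_px
    by_pos = {t.grid_position: t for t in tiles}
    if len(by_pos) != len(tiles):
        raise ValueError("duplicate grid positions")
    for r in range(geometry.tile_rows):
        for c in range(geometry.tile_cols):
            if (r, c) not in by_pos:
                raise ValueError(f"missing tile at grid position {(r, c)}")
            if by_pos[(r, c)].image.shape != (th, tw):
                raise ValueError("tile image shape disagrees with geometry")

    if offsets is None:
        offsets = estimate_offsets(tiles, geometry, refine=refine)

    ov_y, ov_x = geometry.overlap_px
    # canvas extent from actual offsets
    mh = max(oy for oy, _ in offsets.values()) + th
    mw = max(ox for _, ox in offsets.values()) + tw
    num = np.zeros((mh, mw))
    den = np.zeros((mh, mw))
    for (r, c), tile in by_pos.items():
        oy, ox = offsets[(r, c)]
        w = _feather_weight(
            (th, tw),
            (max(ov_y, 1), max(ov_x, 1)),
            top=r > 0,
            bottom=r < geometry.tile_rows - 1,
            left=c > 0,
            right=c < geometry.tile_cols - 1,
        )
        num[oy : oy + th, ox : ox + tw] += w * tile.image.astype(np.float64)
        den[oy : oy + th, ox : ox + tw] += w
    image = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return MosaicFrame(frame=frame, image=image, offsets=dict(offsets))


def _feather_weight(shape, overlap, top, bottom, left, right):
    h, w = shape
    ov_y, ov_x = overlap
    wy = np.ones(h)
    wx = np.ones(w)
    ramp_y = (np.arange(h) + 1.0) / (ov_y + 1.0)
    ramp_x = (np.arange(w) + 1.0) / (ov_x + 1.0)
    if top:
        wy = np.minimum(wy, ramp_y)
    if bottom:
        wy = np.minimum(wy, ramp_y[::-1])
    if left:
        wx = np.minimum(wx, ramp_x)
    if right:
        wx = np.minimum(wx, ramp_x[::-1])
    return wy[:, None] * wx[None, :]


def estimate_offsets(
    tiles: list[ProjectedTile],
    geometry: AcquisitionGeometry,
    refine: bool = True,
) -> dict[tuple[int, int], tuple[int, int]]:
    """Per-tile mosaic offsets; tile (0, 0) is always at (0, 0).

    Offsets are chained: each tile is registered against its left neighbor
    when it has one, otherwise against its top neighbor.
    """
    by_pos = {t.grid_position: t for t in tiles}
    sy, sx = geometry.tile_step_px
    offsets: dict[tuple[int, int], tuple[int, int]] = {(0, 0): (0, 0)}
    for r in range(geometry.tile_rows):
        for c in range(geometry.tile_cols):
            if (r, c) == (0, 0):
                continue
            if c > 0:
                anchor, nominal_shift, axis = (r, c - 1), (0, sx), 1
            else:
                anchor, nominal_shift, axis = (r - 1, c), (sy, 0), 0
            ay, ax = offsets[anchor]
            shift = None
            if refine:
                shift = _refine_pair(
                    by_pos[anchor].image,
                    by_pos[(r, c)].image,
                    nominal_shift,
                    geometry.overlap_px,
                    axis,
                )
                if shift is None:
                    log.warning(
                        "degenerate overlap correlation for tile %s; "
                        "falling back to nominal offset",
                        (r, c),
                    )
            if shift is None:
                shift = nominal_shift
            offsets[(r, c)] = (ay + shift[0], ax + shift[1])
    return offsets


def stitch_series(
    stack: np.ndarray,
    geometry: AcquisitionGeometry,
    method: str = "average",
    refine: bool = True,
    per_frame: bool = False,
) -> list[MosaicFrame]:
    """Project and stitch every frame of a (tile, z, frame, y, x) stack.

    The stage does not move between frames, so by default offsets are
    estimated once on the first frame and reused; ``per_frame`` re-estimates
    them at every time point.
    """
    mosaics = []
    fixed = None
    for t in range(geometry.n_frames):
        tiles = project_tiles(stack, geometry, t, method)
        if per_frame:
            mosaics.append(stitch(tiles, geometry, refine=refine))
            continue
        if fixed is None:
            fixed = estimate_offsets(tiles, geometry, refine=refine)
        mosaics.append(stitch(tiles, geometry, offsets=fixed))
    return mosaics
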