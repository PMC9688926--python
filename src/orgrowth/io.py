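"""File formats: multi-page TIFF stacks with JSON geometry sidecars, CSVs.

Raw recordings are stored as one multi-page TIFF per tile (16-bit unsigned),
page index = ``frame * z_planes + z`` (frames outermost, z within a frame),
next to a ``geometry.json`` sidecar. Mosaic and label series are single
multi-page TIFFs in frame order. All tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import AcquisitionGeometry

SIDECAR_NAME = "geometry.json"


class ImageIOError(RuntimeError):
    """A TIFF stack is unreadable or inconsistent with its geometry."""


def _tile_paths(directory: Path, geometry: AcquisitionGeometry, condition: str):
    return [
        directory / f"{condition}_tile_r{r}c{c}.tif"
        for r in range(geometry.tile_rows)
        for c in range(geometry.tile_cols)
    ]


def write_image_stack(
    directory,
    stack: np.ndarray,
    geometry: AcquisitionGeometry,
    condition: str = "recording",
) -> list[Path]:
    """Write a (tile, z, frame, y, x) stack as per-tile multi-page TIFFs.

    Pages are ordered frame-major (all z of frame 0, then frame 1, ...).
    Writes/overwrites the geometry sidecar next to the tiles.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stack.shape[:3] != (geometry.n_tiles, geometry.z_planes, geometry.n_frames):
        raise ImageIOError(
            f"stack shape {stack.shape} disagrees with geometry "
            f"({geometry.n_tiles} tiles, {geometry.z_planes} z, "
            f"{geometry.n_frames} frames)"
        )
    paths = _tile_paths(directory, geometry, condition)
    for ti, path in enumerate(paths):
        # (z, frame, y, x) -> pages (frame, z)
        pages = np.swapaxes(stack[ti], 0, 1).reshape(-1, *stack.shape[-2:])
        tifffile.imwrite(path, pages.astype(np.uint16))
    geometry.save_json(directory / SIDECAR_NAME)
    return paths


def read_image_stack(
    directory,
    geometry: AcquisitionGeometry | None = None,
    condition: str = "recording",
) -> tuple[np.ndarray, AcquisitionGeometry]:
    """Read a per-tile TIFF stack back to (tile, z, frame, y, x).

    Geometry comes from the sidecar unless passed explicitly; a missing
    sidecar without an explicit geometry, a page-count mismatch, or an
    unreadable file raise :class:`ImageIOError` naming the offender.
    """
    directory = Path(directory)
    if geometry is None:
        sidecar = directory / SIDECAR_NAME
        if not sidecar.exists():
            raise ImageIOError(
                f"no geometry sidecar at {sidecar}; pass geometry explicitly"
            )
        geometry = AcquisitionGeometry.load_json(sidecar)
    th, tw = geometry.tile_shape_px
    out = np.empty(
        (geometry.n_tiles, geometry.z_planes, geometry.n_frames, th, tw),
        dtype=np.uint16,
    )
    for ti, path in enumerate(_tile_paths(directory, geometry, condition)):
        if not path.exists():
            raise ImageIOError(f"missing tile file {path}")
        try:
            pages = tifffile.imread(path)
        except Exception as exc:  # corrupt file
            raise ImageIOError(f"unreadable TIFF {path}: {exc}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        expected = geometry.n_frames * geometry.z_planes
        if pages.shape[0] != expected or pages.shape[-2:] != (th, tw):
            raise ImageIOError(
                f"{path}: {pages.shape[0]} pages of {pages.shape[-2:]}, "
                f"expected {expected} pages of {(th, tw)}"
            )
        out[ti] = np.swapaxes(
            pages.reshape(geometry.n_frames, geometry.z_planes, th, tw), 0, 1
        )
    return out, geometry


def write_frame_series(path, images: list[np.ndarray], dtype=None) -> Path:
    """Write a list of equal-shape 2D frames as one multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.stack(images)
    if dtype is not None:
        arr = arr.astype(dtype)
    tifffile.imwrite(path, arr)
    return path


def read_frame_series(path) -> np.ndarray:
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ImageIOError(f"unreadable TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_manifest(path, stage: str, params: dict, inputs: list[str], seed) -> None:
    """Stage manifest enabling bit-identical re-runs (no timestamps)."""
    import orgrowth

    payload = {
        "stage": stage,
        "package_version": orgrowth.__version__,
        "seed": seed,
        "inputs": sorted(str(i) for i in inputs),
        "params": params,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
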