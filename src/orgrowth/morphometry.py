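"""Region morphometry: per-label area, centroid, perimeter, circularity.

Areas are pixel counts scaled by the squared pixel size; the perimeter is
the 4-connected crack length (count of unit boundary steps between a region
pixel and anything else, including the image border), so a 10x10 square has
perimeter 40 px. Circularity is 4*pi*area/perimeter^2 under that estimator:
1 is unreachable for digital shapes, digital disks converge to pi^2/16.
Alternative perimeter estimators can be plugged in via ``perimeter_fn``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import LabeledFrame

REGION_COLUMNS = [
    "frame",
    "label",
    "area_um2",
    "cx_um",
    "cy_um",
    "perimeter_um",
    "circularity",
    "touches_border",
]


@dataclass(frozen=True)
class RegionRecord:
    """Schema of one measured region (one row of the regions table)."""

    frame: int
    label: int
    area_um2: float
    cx_um: float
    cy_um: float
    perimeter_um: float
    circularity: float
    touches_border: bool


def crack_perimeter_px(labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """4-connected crack-length perimeter (in pixel units) per label."""
    padded = np.pad(labels, 1, constant_values=0)
    counts = np.zeros(ids.max() + 1, dtype=np.int64) if ids.size else np.zeros(1, int)
    core = padded[1:-1, 1:-1]
    for shifted in (
        padded[:-2, 1:-1],
        padded[2:, 1:-1],
        padded[1:-1, :-2],
        padded[1:-1, 2:],
    ):
        mask = (core > 0) & (core != shifted)
        if mask.any():
            counts += np.bincount(core[mask], minlength=counts.size)
    return counts[ids]


def measure_regions(
    labeled: LabeledFrame | np.ndarray,
    pixel_size_um: float,
    pixel_units: bool = False,
    perimeter_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = crack_perimeter_px,
) -> pd.DataFrame:
    """Measure every labeled region of a frame.

    Returns a table with one row per label (columns ``REGION_COLUMNS``).
    Centroids are means of pixel centers, scaled to um; ``pixel_units``
    reports areas/lengths in px^2/px instead. An empty frame gives an
    empty table.
    """
    if isinstance(labeled, LabeledFrame):
        labels, frame = labeled.labels, labeled.frame
    else:
        labels, frame = np.asarray(labeled), 0
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(columns=REGION_COLUMNS).astype(
            {"frame": int, "label": int, "touches_border": bool}
        )
    scale = 1.0 if pixel_units else pixel_size_um
    counts = np.bincount(labels[labels > 0], minlength=ids.max() + 1)[ids]
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    cy = np.array([c[0] for c in centroids]) * scale
    cx = np.array([c[1] for c in centroids]) * scale
    perim = perimeter_fn(labels, ids).astype(np.float64) * scale
    area = counts.astype(np.float64) * scale**2
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = np.where(perim > 0, 4.0 * np.pi * area / perim**2, np.nan)
    border = np.concatenate(
        [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
    )
    border_ids = set(int(v) for v in np.unique(border) if v > 0)
    return pd.DataFrame(
        {
            "frame": frame,
            "label": ids.astype(int),
            "area_um2": area,
            "cx_um": cx,
            "cy_um": cy,
            "perimeter_um": perim,
            "circularity": circ,
            "touches_border": [int(i) in border_ids for i in ids],
        }
    )


def measure_frames(
    frames: list[LabeledFrame], pixel_size_um: float, **kw
) -> pd.DataFrame:
    """Concatenate measurements over a frame series."""
    parts = [measure_regions(f, pixel_size_um, **kw) for f in frames]
    non_empty = [p for p in parts if len(p)]
    if not non_empty:
        return parts[0] if parts else pd.DataFrame(columns=REGION_COLUMNS)
    return pd.concat(non_empty, ignore_index=True)
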