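"""Synthetic brightfield-like organoid time-lapse generator.

Emulates label-free recordings of cystic organoid cultures: each organoid is
a bright luminal disk bounded by a darker epithelial ring, growing
exponentially with a condition-specific inhibition factor. The generator
produces the raw tile x z x frame stacks the preprocessing stage consumes,
plus a ground-truth table of per-frame centers, radii and areas against
which every downstream stage can be validated.

Model
-----
Luminal area follows ``A(t) = A(0) * exp(g * (1 - eta) * t)`` where ``g`` is
the base per-hour growth rate and ``eta`` in [0, 1] the condition's growth
inhibition, so the radius grows as ``r(t) = r(0) * exp(g (1 - eta) t / 2)``.
Each condition is an independent well (its own recording); organoid centers
are placed by rejection sampling so epithelial rims never initially overlap
and keep headroom for growth. Optics are reduced to a per-organoid focal
plane with Gaussian defocus whose sigma grows linearly with distance from
that plane; edges are rendered analytically with erf-profiles. A smooth
linear illumination gradient and additive Gaussian noise complete the image
model. Intensity statistics are synthetic conveniences, not measurements of
any real microscope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erfc

from .geometry import AcquisitionGeometry

GROUND_TRUTH_COLUMNS = [
    "organoid_id",
    "condition",
    "frame",
    "cx_um",
    "cy_um",
    "lumen_radius_um",
    "true_lumen_area_um2",
    "visible",
]


#: Ground-truth tables are plain DataFrames with :data:`GROUND_TRUTH_COLUMNS`
#: (one row per organoid per frame).
GroundTruth = pd.DataFrame


class PackingError(RuntimeError):
    """Raised when organoid centers cannot be placed without rim overlap."""


@dataclass
class SimulationConfig:
    """Everything that determines one synthetic experiment.

    ``conditions`` maps condition name -> growth inhibition eta in [0, 1];
    each condition is rendered as an independent well. ``seed`` fixes every
    stochastic draw (placement, focal planes, illumination, noise, dropout)
    end to end.
    """

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    n_organoids: int = 60
    conditions: list[tuple[str, float]] = field(
        default_factory=lambda: [("untreated", 0.0)]
    )
    #: per-hour exponential rate; default doubles area 2.3x over 48 h,
    #: matching a vigorously growing untreated culture
    base_growth_rate_per_h: float = math.log(2.3) / 48.0
    #: (median, sigma of log) of the lognormal initial lumen radius draw
    initial_radius_um: tuple[float, float] = (20.0, 0.12)
    epithelial_ring_thickness_um: float = 6.0
    noise_sd: float = 300.0
    illumination_gradient_amplitude: float = 0.08
    dropout_prob_per_frame: float = 0.0
    seed: int = 0
    # rendering levels (16-bit counts); polarity is configurable but the
    # default is the bright-lumen / dark-rim appearance of cystic organoids
    background_level: float = 10000.0
    lumen_level: float = 22000.0
    ring_level: float = 4000.0
    #: in-focus edge softness (px) and defocus growth (px per um of defocus)
    focus_sigma_px: float = 0.8
    defocus_px_per_um: float = 0.03
    #: center separation must exceed margin * sum of final outer radii
    placement_margin: float = 1.05
    max_placement_tries: int = 5000

    def __post_init__(self) -> None:
        if self.n_organoids < 1:
            raise ValueError("n_organoids must be >= 1")
        for name, eta in self.conditions:
            if not (0.0 <= eta <= 1.0):
                raise ValueError(f"inhibition eta for {name!r} outside [0, 1]")
        if not (0.0 <= self.dropout_prob_per_frame < 1.0):
            raise ValueError("dropout_prob_per_frame must lie in [0, 1)")
        if self.initial_radius_um[0] <= 0:
            raise ValueError("initial radius must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["conditions"] = [list(c) for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["geometry"] = AcquisitionGeometry.from_dict(d["geometry"])
        d["conditions"] = [tuple(c) for c in d["conditions"]]
        d["initial_radius_um"] = tuple(d["initial_radius_um"])
        return cls(**d)


def frame_count(duration_h: float, interval_h: float) -> int:
    """Number of time points for a recording of ``duration_h`` hours.

    Counting 0 h as the first time point: 48 h at a 0.5 h interval gives 97.
    The interval must divide the duration exactly.
    """
    if interval_h <= 0:
        raise ValueError("interval_h must be positive")
    if duration_h < 0:
        raise ValueError("duration_h must be non-negative")
    n = duration_h / interval_h
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"interval {interval_h} h does not divide duration {duration_h} h"
        )
    return int(round(n)) + 1


# ---------------------------------------------------------------------------
# placement and rendering internals


def _place_centers(
    rng: np.random.Generator,
    n: int,
    extent_um: tuple[float, float],
    outer_radii_final_um: np.ndarray,
    margin: float,
    max_tries: int,
) -> np.ndarray:
    """Rejection-sample non-overlapping centers; returns (n, 2) [x, y] um."""
    h_um, w_um = extent_um
    centers = np.empty((n, 2))
    placed = 0
    tries = 0
    order = np.argsort(outer_radii_final_um)[::-1]  # big ones first
    radii = outer_radii_final_um[order]
    while placed < n:
        if tries >= max_tries * n:
            area = h_um * w_um
            fill = float(np.sum(np.pi * outer_radii_final_um**2) / area)
            raise PackingError(
                f"could not place {n} organoids in a {w_um:.0f} x {h_um:.0f} um "
                f"field (projected fill factor {fill:.0%} at final size); "
                "reduce n_organoids, initial_radius_um, or growth"
            )
        tries += 1
        r = radii[placed]
        x = rng.uniform(r, w_um - r)
        y = rng.uniform(r, h_um - r)
        if placed:
            d = np.hypot(centers[:placed, 0] - x, centers[:placed, 1] - y)
            if np.any(d < margin * (radii[:placed] + r)):
                continue
        centers[placed] = (x, y)
        placed += 1
    out = np.empty_like(centers)
    out[order] = centers
    return out


def _render_organoid(
    scene: np.ndarray,
    cx_px: float,
    cy_px: float,
    lumen_r_px: float,
    ring_px: float,
    sigma_px: float,
    lumen_amp: float,
    ring_amp: float,
) -> None:
    """Add one organoid (bright lumen, dark rim) to the scene in place.

    Radial profile built from two erf edge steps: ring_amp applies out to the
    outer rim radius, lumen_amp on top of it inside the lumen.
    """
    pad = lumen_r_px + ring_px + 4.0 * sigma_px + 2.0
    h, w = scene.shape
    y0 = max(int(cy_px - pad), 0)
    y1 = min(int(cy_px + pad) + 2, h)
    x0 = max(int(cx_px - pad), 0)
    x1 = min(int(cx_px + pad) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=np.float64)[:, None] - cy_px
    xx = np.arange(x0, x1, dtype=np.float64)[None, :] - cx_px
    r = np.hypot(yy, xx)
    s = sigma_px * math.sqrt(2.0)
    inner = 0.5 * erfc((r - lumen_r_px) / s)
    outer = 0.5 * erfc((r - (lumen_r_px + ring_px)) / s)
    scene[y0:y1, x0:x1] += ring_amp * outer + (lumen_amp - ring_amp) * inner


def simulate_recording(
    config: SimulationConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Simulate one recording per condition.

    Returns ``(stacks, ground_truth)`` where ``stacks[condition]`` is a
    uint16 array of shape (n_tiles, z_planes, n_frames, tile_h, tile_w) with
    tiles in row-major grid order, and ``ground_truth`` is a table with one
    row per (organoid, frame) following :data:`GROUND_TRUTH_COLUMNS`.
    Identical configs (same seed) yield bit-identical outputs.
    """
    g = config.geometry
    px = g.pixel_size_um
    mh, mw = g.mosaic_shape_px
    extent_um = (mh * px, mw * px)
    times = np.arange(g.n_frames) * g.interval_h
    rng = np.random.default_rng(config.seed)

    stacks: dict[str, np.ndarray] = {}
    gt_rows: list[pd.DataFrame] = []
    next_id = 1
    for name, eta in config.conditions:
        rate = config.base_growth_rate_per_h * (1.0 - eta)
        radius_growth = math.exp(0.5 * rate * times[-1]) if g.n_frames > 1 else 1.0

        r0 = config.initial_radius_um[0] * np.exp(
            rng.normal(0.0, config.initial_radius_um[1], config.n_organoids)
        )
        outer_final = r0 * radius_growth + config.epithelial_ring_thickness_um
        centers = _place_centers(
            rng,
            config.n_organoids,
            extent_um,
            outer_final,
            config.placement_margin,
            config.max_placement_tries,
        )
        # per-organoid focal plane: one of the acquired z positions
        focal_idx = rng.integers(0, g.z_planes, config.n_organoids)
        focal_um = focal_idx * g.z_spacing_um
        # smooth illumination gradient, one orientation per well
        theta = rng.uniform(0.0, 2.0 * np.pi)
        amp = config.illumination_gradient_amplitude
        yy = (np.arange(mh) / max(mh - 1, 1) - 0.5)[:, None]
        xx = (np.arange(mw) / max(mw - 1, 1) - 0.5)[None, :]
        illum = 1.0 + 2.0 * amp * (np.cos(theta) * xx + np.sin(theta) * yy)

        visible = np.ones((config.n_organoids, g.n_frames), dtype=bool)
        if config.dropout_prob_per_frame > 0:
            visible = (
                rng.random((config.n_organoids, g.n_frames))
                >= config.dropout_prob_per_frame
            )

        radii_t = r0[:, None] * np.exp(0.5 * rate * times[None, :])

        stack = np.empty(
            (g.n_tiles, g.z_planes, g.n_frames, *g.tile_shape_px), dtype=np.uint16
        )
        lumen_amp = config.lumen_level - config.background_level
        ring_amp = config.ring_level - config.background_level
        for t in range(g.n_frames):
            for zi in range(g.z_planes):
                scene = np.full((mh, mw), config.background_level)
                z_um = zi * g.z_spacing_um
                for k in range(config.n_organoids):
                    if not visible[k, t]:
                        continue
                    sigma = (
                        config.focus_sigma_px
                        + config.defocus_px_per_um * abs(z_um - focal_um[k])
                    )
                    _render_organoid(
                        scene,
                        centers[k, 0] / px,
                        centers[k, 1] / px,
                        radii_t[k, t] / px,
                        config.epithelial_ring_thickness_um / px,
                        sigma,
                        lumen_amp,
                        ring_amp,
                    )
                scene *= illum
                scene += rng.normal(0.0, config.noise_sd, scene.shape)
                np.clip(scene, 0, 65535, out=scene)
                scene16 = scene.astype(np.uint16)
                for ti, (row, col) in enumerate(
                    [(r, c) for r in range(g.tile_rows) for c in range(g.tile_cols)]
                ):
                    oy, ox = g.nominal_offset(row, col)
                    th, tw = g.tile_shape_px
                    stack[ti, zi, t] = scene16[oy : oy + th, ox : ox + tw]
        stacks[name] = stack

        ids = np.arange(next_id, next_id + config.n_organoids)
        next_id += config.n_organoids
        gt = pd.DataFrame(
            {
                "organoid_id": np.repeat(ids, g.n_frames),
                "condition": name,
                "frame": np.tile(np.arange(g.n_frames), config.n_organoids),
                "cx_um": np.repeat(centers[:, 0], g.n_frames),
                "cy_um": np.repeat(centers[:, 1], g.n_frames),
                "lumen_radius_um": radii_t.ravel(),
                "true_lumen_area_um2": np.pi * radii_t.ravel() ** 2,
                "visible": visible.ravel(),
            }
        )
        gt_rows.append(gt)

    ground_truth = pd.concat(gt_rows, ignore_index=True)[GROUND_TRUTH_COLUMNS]
    return stacks, ground_truth


def write_ground_truth(gt: pd.DataFrame, path) -> None:
    """Write the ground-truth table to CSV (round-trips via read_ground_truth)."""
    out = gt.loc[:, GROUND_TRUTH_COLUMNS] if len(gt) else gt.reindex(
        columns=GROUND_TRUTH_COLUMNS
    )
    out.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    gt = pd.read_csv(
        Path(path),
        dtype={"organoid_id": int, "frame": int, "condition": str, "visible": bool},
    )
    return gt[GROUND_TRUTH_COLUMNS] if len(gt.columns) else gt
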