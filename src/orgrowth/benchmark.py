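"""A self-contained two-condition recovery benchmark.

Simulates an untreated well and a growth-inhibited well whose *true* final
area ratio is known, runs the full pipeline on the raw synthetic recordings,
and reports how well the relative-size readout recovers the programmed
contrast. Scaled down relative to a full-size recording (256x256 px tiles,
3 z-planes) so it runs in minutes on one CPU, but keeping the full 97
half-hour frames and a culture size inside the observed 41-139 range.
"""

from __future__ import annotations

import math

from .config import AnalysisParams, PipelineConfig
from .geometry import AcquisitionGeometry
from .segmentation import SegmentationParams
from .simulate import SimulationConfig


def two_condition_benchmark_config(
    seed: int,
    output_dir: str,
    true_final_ratio: float = 0.49,
    n_organoids: int = 42,
    n_frames: int = 97,
) -> PipelineConfig:
    """Pipeline config for the recovery benchmark.

    ``true_final_ratio`` is the ground-truth treated/untreated final-area
    ratio; the treated well's inhibition is ``eta = -ln(ratio)/ln(2.3)`` so
    that the untreated well grows 2.3x over 48 h and the treated one
    ``2.3 * ratio``.
    """
    if not (0.0 < true_final_ratio <= 1.0):
        raise ValueError("true_final_ratio must lie in (0, 1]")
    eta = -math.log(true_final_ratio) / math.log(2.3)
    sim = SimulationConfig(
        geometry=AcquisitionGeometry(
            tile_shape_px=(256, 256), z_planes=3, n_frames=n_frames
        ),
        n_organoids=n_organoids,
        conditions=[("untreated", 0.0), ("treated", eta)],
        initial_radius_um=(15.0, 0.12),
        epithelial_ring_thickness_um=5.0,
        seed=seed,
    )
    return PipelineConfig(
        simulation=sim,
        segmentation=SegmentationParams(min_area_um2=250.0),
        analysis=AnalysisParams(reference_condition="untreated"),
        output_dir=output_dir,
    )
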