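"""Pipeline configuration: one structured file driving every stage.

The config bundles the simulation, segmentation, linking, analysis and
statistics parameter blocks plus paths and the master seed. Every block is
validated on construction, before any stage runs, and the file round-trips
load -> save -> load identically (YAML or JSON by extension).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .geometry import AcquisitionGeometry
from .segmentation import SegmentationParams
from .simulate import SimulationConfig
from .tracking import LinkingParams


@dataclass
class AnalysisParams:
    """Growth-analysis block: baseline window, reference and dose contrast."""

    baseline_window: int = 5
    reference_condition: str = "untreated"
    dose_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")
        if self.dose_pair is not None:
            self.dose_pair = tuple(self.dose_pair)  # type: ignore[assignment]
            if len(self.dose_pair) != 2:
                raise ValueError("dose_pair must name exactly two conditions")


@dataclass
class StatsParams:
    alpha: float = 0.05
    mw_exact_threshold: int = 8
    posthoc_method: str = "dunn"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.posthoc_method not in ("dunn", "pairwise_mw"):
            raise ValueError("posthoc_method must be 'dunn' or 'pairwise_mw'")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    stats: StatsParams = field(default_factory=StatsParams)
    output_dir: str = "orgrowth_out"
    projection_method: str = "average"
    refine_stitching: bool = True
    stitch_per_frame: bool = False
    log_level: str = "INFO"

    @property
    def geometry(self) -> AcquisitionGeometry:
        return self.simulation.geometry

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["analysis"]["dose_pair"] = (
            list(self.analysis.dose_pair) if self.analysis.dose_pair else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams.from_dict(d["segmentation"])
        if "linking" in d:
            d["linking"] = LinkingParams(**d["linking"])
        if "analysis" in d:
            d["analysis"] = AnalysisParams(**d["analysis"])
        if "stats" in d:
            d["stats"] = StatsParams(**d["stats"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(raw)
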