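"""End-to-end orchestration of the growth-analysis pipeline.

Stages (in order): ``simulate`` -> ``stitch`` (z-projection + tile
stitching) -> ``segment`` -> ``measure`` -> ``track`` -> ``analyze`` (NPA
curves, median curves, relative sizes) -> ``stats`` (Mann-Whitney of every
condition's median NPA series against the reference). Each stage reads its
inputs from the artifact directory, writes its outputs plus a manifest
(stage, parameters, inputs, seed, package version), and a re-run with the
same config is bit-identical. Any subset of stages can be run provided the
upstream artifacts exist.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, io, morphometry, simulate, stats, tracking
from .config import PipelineConfig
from .preprocess import stitch_series
from .segmentation import LabeledFrame, segment_frame

log = logging.getLogger(__name__)

STAGES = ("simulate", "stitch", "segment", "measure", "track", "analyze", "stats")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _conditions(config: PipelineConfig) -> list[str]:
    return [name for name, _ in config.simulation.conditions]


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing upstream artifact {path}")
    return path


def run_pipeline(
    config: PipelineConfig, stages: set[str] | None = None
) -> Path:
    """Run the requested stages (default: all) into ``config.output_dir``."""
    wanted = set(STAGES) if stages is None else set(stages)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    (out / "manifests").mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    for stage in STAGES:
        if stage in wanted:
            _RUNNERS[stage](config, out)
    return out


def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    try:
        stacks, gt = simulate.simulate_recording(config.simulation)
    except simulate.PackingError as exc:
        raise StageError("simulate", str(exc)) from exc
    raw = out / "raw"
    for cond, stack in stacks.items():
        io.write_image_stack(raw, stack, config.geometry, condition=cond)
    simulate.write_ground_truth(gt, out / "ground_truth.csv")
    io.write_manifest(
        out / "manifests" / "simulate.json",
        "simulate",
        config.simulation.to_dict(),
        [],
        config.seed,
    )
    log.info("simulate: %d conditions, %d organoids each",
             len(stacks), config.simulation.n_organoids)


def _stage_stitch(config: PipelineConfig, out: Path) -> None:
    g = config.geometry
    raw = _require("stitch", out / "raw")
    (out / "mosaics").mkdir(exist_ok=True)
    for cond in _conditions(config):
        try:
            stack, _ = io.read_image_stack(raw, g, condition=cond)
        except io.ImageIOError as exc:
            raise StageError("stitch", str(exc)) from exc
        mosaics = stitch_series(
            stack,
            g,
            method=config.projection_method,
            refine=config.refine_stitching,
            per_frame=config.stitch_per_frame,
        )
        io.write_frame_series(
            out / "mosaics" / f"{cond}.tif",
            [np.clip(np.rint(m.image), 0, 65535) for m in mosaics],
            dtype=np.uint16,
        )
        rows = [
            (m.frame, r, c, oy, ox)
            for m in mosaics
            for (r, c), (oy, ox) in sorted(m.offsets.items())
        ]
        pd.DataFrame(
            rows, columns=["frame", "tile_row", "tile_col", "dy_px", "dx_px"]
        ).to_csv(out / "mosaics" / f"{cond}_offsets.csv", index=False)
    io.write_manifest(
        out / "manifests" / "stitch.json",
        "stitch",
        {
            "projection_method": config.projection_method,
            "refine": config.refine_stitching,
            "per_frame": config.stitch_per_frame,
        },
        [str(raw)],
        config.seed,
    )


def _labeled_frames(path: Path) -> list[LabeledFrame]:
    arr = io.read_frame_series(path)
    return [
        LabeledFrame(frame=t, labels=arr[t].astype(np.int32),
                     n_objects=int(arr[t].max()))
        for t in range(arr.shape[0])
    ]


def _stage_segment(config: PipelineConfig, out: Path) -> None:
    g = config.geometry
    (out / "labels").mkdir(exist_ok=True)
    n_objects = []
    for cond in _conditions(config):
        src = _require("segment", out / "mosaics" / f"{cond}.tif")
        try:
            mosaics = io.read_frame_series(src)
        except io.ImageIOError as exc:
            raise StageError("segment", str(exc)) from exc
        labeled = [
            segment_frame(mosaics[t], config.segmentation, g.pixel_size_um, frame=t)
            for t in range(mosaics.shape[0])
        ]
        n_objects.append((cond, [lf.n_objects for lf in labeled]))
        io.write_frame_series(
            out / "labels" / f"{cond}.tif",
            [lf.labels for lf in labeled],
            dtype=np.uint16,
        )
    for cond, counts in n_objects:
        log.info("segment[%s]: %.1f objects/frame (min %d, max %d)",
                 cond, float(np.mean(counts)), min(counts), max(counts))
    io.write_manifest(
        out / "manifests" / "segment.json",
        "segment",
        config.segmentation.to_dict(),
        [str(out / "mosaics")],
        config.seed,
    )


def _stage_measure(config: PipelineConfig, out: Path) -> None:
    g = config.geometry
    (out / "regions").mkdir(exist_ok=True)
    for cond in _conditions(config):
        src = _require("measure", out / "labels" / f"{cond}.tif")
        frames = _labeled_frames(src)
        df = morphometry.measure_frames(frames, g.pixel_size_um)
        df.to_csv(out / "regions" / f"{cond}.csv", index=False)
    io.write_manifest(
        out / "manifests" / "measure.json",
        "measure",
        {"pixel_size_um": g.pixel_size_um},
        [str(out / "labels")],
        config.seed,
    )


def _stage_track(config: PipelineConfig, out: Path) -> None:
    g = config.geometry
    (out / "tracks").mkdir(exist_ok=True)
    for cond in _conditions(config):
        labels_path = _require("track", out / "labels" / f"{cond}.tif")
        regions_path = _require("track", out / "regions" / f"{cond}.csv")
        frames = _labeled_frames(labels_path)
        regions = pd.read_csv(regions_path)
        tracks = tracking.link_frames(frames, regions, config.linking,
                                      g.pixel_size_um)
        tracking.tracks_to_dataframe(tracks).to_csv(
            out / "tracks" / f"{cond}.csv", index=False
        )
        summary = tracking.track_summary(tracks, g.n_frames)
        summary.to_csv(out / "tracks" / f"{cond}_summary.csv", index=False)
        n_complete = int(summary["complete"].sum())
        log.info(
            "track[%s]: %d tracks, %d complete, %d excluded by the "
            "all-frames rule", cond, len(tracks), n_complete,
            len(tracks) - n_complete,
        )
    io.write_manifest(
        out / "manifests" / "track.json",
        "track",
        {"min_iou": config.linking.min_iou,
         "max_centroid_shift_um": config.linking.max_centroid_shift_um},
        [str(out / "labels"), str(out / "regions")],
        config.seed,
    )


def _stage_analyze(config: PipelineConfig, out: Path) -> None:
    g = config.geometry
    (out / "npa").mkdir(exist_ok=True)
    summaries = []
    for cond in _conditions(config):
        src = _require("analyze", out / "tracks" / f"{cond}.csv")
        tracks = tracking.tracks_from_dataframe(pd.read_csv(src))
        complete = tracking.filter_complete(tracks, g.n_frames)
        if not complete:
            raise StageError("analyze", f"no complete tracks for {cond!r}")
        curves = [
            growth.compute_npa(t, config.analysis.baseline_window, condition=cond)
            for t in complete
        ]
        growth.npa_dataframe(curves).to_csv(out / "npa" / f"{cond}.csv", index=False)
        summaries.append(growth.condition_median_curve(curves))
    growth.median_curves_dataframe(summaries).to_csv(
        out / "median_curves.csv", index=False
    )
    table = growth.relative_size_table(
        summaries, config.analysis.reference_condition, config.analysis.dose_pair
    )
    table.to_dataframe().to_csv(out / "relative_sizes.csv", index=False)
    io.write_manifest(
        out / "manifests" / "analyze.json",
        "analyze",
        {"baseline_window": config.analysis.baseline_window,
         "reference": config.analysis.reference_condition},
        [str(out / "tracks")],
        config.seed,
    )


def _stage_stats(config: PipelineConfig, out: Path) -> None:
    src = _require("stats", out / "median_curves.csv")
    med = pd.read_csv(src)
    ref = config.analysis.reference_condition
    if ref not in set(med["condition"]):
        raise StageError("stats", f"reference condition {ref!r} not in medians")
    ref_series = med.loc[med["condition"] == ref, "median_npa"].to_numpy()
    results = []
    for cond in _conditions(config):
        if cond == ref:
            continue
        series = med.loc[med["condition"] == cond, "median_npa"].to_numpy()
        r = stats.mann_whitney_u(
            ref_series, series, exact_threshold=config.stats.mw_exact_threshold
        )
        r.details["pair"] = (ref, cond)
        results.append(r)
    stats.results_to_dataframe(results).to_csv(out / "stats.csv", index=False)
    io.write_manifest(
        out / "manifests" / "stats.json",
        "stats",
        {"alpha": config.stats.alpha,
         "mw_exact_threshold": config.stats.mw_exact_threshold},
        [str(src)],
        config.seed,
    )


_RUNNERS = {
    "simulate": _stage_simulate,
    "stitch": _stage_stitch,
    "segment": _stage_segment,
    "measure": _stage_measure,
    "track": _stage_track,
    "analyze": _stage_analyze,
    "stats": _stage_stats,
}
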