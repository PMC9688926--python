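"""Link per-frame regions into per-organoid trajectories.

Identity across frames is assigned by greedy one-to-one matching on region
overlap (intersection over union) between each frame and the most recent
detected footprint of every open track, gated by a minimum IoU and a maximum
centroid displacement. Organoids are effectively stationary, so overlap is a
reliable identity cue; the linker replaces the manual bookkeeping of the
original analysis workflow and is the package's principal departure from it.

A track that goes undetected in a frame records a MISSING entry but stays
open and may re-link when the object reappears; the completeness filter
(an organoid must be detected in every frame of the recording) then excludes
any track with gaps, and any track that started after the first frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import LabeledFrame

TRACK_COLUMNS = [
    "organoid_id",
    "frame",
    "label",
    "area_um2",
    "cx_um",
    "cy_um",
    "missing",
]


@dataclass
class LinkingParams:
    min_iou: float = 0.3
    max_centroid_shift_um: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_iou <= 1.0):
            raise ValueError("min_iou must lie in [0, 1]")
        if self.max_centroid_shift_um <= 0:
            raise ValueError("max_centroid_shift_um must be positive")


@dataclass
class TrackEntry:
    frame: int
    label: int | None  # None = MISSING in this frame
    area_um2: float
    cx_um: float
    cy_um: float

    @property
    def missing(self) -> bool:
        return self.label is None


@dataclass
class Track:
    organoid_id: int
    entries: list[TrackEntry] = field(default_factory=list)

    @property
    def n_detected(self) -> int:
        return sum(not e.missing for e in self.entries)

    @property
    def first_frame(self) -> int:
        return self.entries[0].frame if self.entries else -1

    def is_complete(self, n_frames: int) -> bool:
        return self.n_detected == n_frames

    def areas(self) -> np.ndarray:
        return np.array([e.area_um2 for e in self.entries])


def link_frames(
    frames: list[LabeledFrame],
    regions: pd.DataFrame,
    params: LinkingParams | None = None,
    pixel_size_um: float = 1.0,
) -> list[Track]:
    """Link a temporal series of label images into tracks.

    ``regions`` must carry (frame, label, area_um2, cx_um, cy_um) rows for
    every labeled region (see ``morphometry.measure_regions``). Matching per
    frame is greedy by descending IoU against each open track's last
    detected footprint; ties break by (smaller track id, smaller label).
    """
    if not frames:
        raise ValueError("no frames to link")
    params = params or LinkingParams()
    reg = {
        (int(r.frame), int(r.label)): r
        for r in regions.itertuples(index=False)
    }

    tracks: list[Track] = []
    canvas = np.zeros_like(frames[0].labels, dtype=np.int64)  # track footprints
    track_area_px: dict[int, int] = {}
    track_centroid: dict[int, tuple[float, float]] = {}
    open_at_frame: set[int] = set()

    def start_track(frame_idx: int, lab: int, labels: np.ndarray) -> None:
        tid = len(tracks) + 1
        r = reg[(frame_idx, lab)]
        tracks.append(
            Track(tid, [TrackEntry(frame_idx, lab, r.area_um2, r.cx_um, r.cy_um)])
        )
        mask = labels == lab
        canvas[mask] = tid
        track_area_px[tid] = int(mask.sum())
        track_centroid[tid] = (r.cx_um, r.cy_um)
        open_at_frame.add(tid)

    first = frames[0]
    for lab in range(1, first.n_objects + 1):
        start_track(first.frame, lab, first.labels)

    for lf in frames[1:]:
        labels = lf.labels
        n_lab = lf.n_objects
        lab_area = np.bincount(labels[labels > 0], minlength=n_lab + 1)
        # joint histogram canvas x labels over jointly-positive pixels
        both = (canvas > 0) & (labels > 0)
        cand: list[tuple[float, int, int]] = []
        if both.any():
            codes = canvas[both] * (n_lab + 1) + labels[both]
            inter = np.bincount(codes)
            nz = np.flatnonzero(inter)
            for code in nz:
                tid, lab = divmod(int(code), n_lab + 1)
                if lab == 0 or tid == 0:
                    continue
                i = inter[code]
                union = track_area_px[tid] + lab_area[lab] - i
                iou = i / union
                if iou < params.min_iou:
                    continue
                r = reg[(lf.frame, lab)]
                cx, cy = track_centroid[tid]
                shift = math.hypot(r.cx_um - cx, r.cy_um - cy)
                if shift > params.max_centroid_shift_um:
                    continue
                cand.append((iou, tid, lab))
        cand.sort(key=lambda t: (-t[0], t[1], t[2]))
        matched_t: dict[int, int] = {}
        matched_l: set[int] = set()
        for iou, tid, lab in cand:
            if tid in matched_t or lab in matched_l:
                continue
            matched_t[tid] = lab
            matched_l.add(lab)

        # update canvas: matched tracks move to their new footprint
        if matched_t:
            canvas[np.isin(canvas, list(matched_t))] = 0
        for tid, lab in sorted(matched_t.items()):
            r = reg[(lf.frame, lab)]
            tracks[tid - 1].entries.append(
                TrackEntry(lf.frame, lab, r.area_um2, r.cx_um, r.cy_um)
            )
            mask = labels == lab
            canvas[mask] = tid
            track_area_px[tid] = int(mask.sum())
            track_centroid[tid] = (r.cx_um, r.cy_um)
        for tid in sorted(open_at_frame - set(matched_t)):
            cx, cy = track_centroid[tid]
            tracks[tid - 1].entries.append(
                TrackEntry(lf.frame, None, float("nan"), cx, cy)
            )
        for lab in range(1, n_lab + 1):
            if lab not in matched_l:
                start_track(lf.frame, lab, labels)
    return tracks


def filter_complete(tracks: list[Track], n_frames: int) -> list[Track]:
    """Keep exactly the tracks detected in all ``n_frames`` frames."""
    return [t for t in tracks if t.n_detected == n_frames]


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (t.organoid_id, e.frame, -1 if e.label is None else e.label,
         e.area_um2, e.cx_um, e.cy_um, e.missing)
        for t in tracks
        for e in t.entries
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in df.groupby("organoid_id", sort=True):
        entries = [
            TrackEntry(
                int(r.frame),
                None if (r.missing or r.label < 0) else int(r.label),
                float(r.area_um2),
                float(r.cx_um),
                float(r.cy_um),
            )
            for r in grp.sort_values("frame").itertuples(index=False)
        ]
        tracks.append(Track(int(tid), entries))
    return tracks


def track_summary(tracks: list[Track], n_frames: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "organoid_id": [t.organoid_id for t in tracks],
            "n_detected": [t.n_detected for t in tracks],
            "complete": [t.is_complete(n_frames) for t in tracks],
        }
    )
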