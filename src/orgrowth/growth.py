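"""Normalized projected area (NPA) growth curves and relative-size summary.

Each complete track's projected luminal areas are normalized to the mean
area over the first ``window`` (default 5) time points, giving a
dimensionless NPA curve with baseline 1. Per condition, the per-frame
median across organoids summarizes the culture; the relative-size table
compares each condition's final median NPA with an untreated reference as
an integer percentage (rounded half away from zero), plus the signed
difference vs 100 and an optional high-vs-low dose ratio row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import Track


@dataclass
class NPACurve:
    organoid_id: int
    condition: str
    baseline_area_um2: float
    npa: np.ndarray
    window: int = 5


@dataclass
class ConditionSummary:
    condition: str
    median_npa: np.ndarray
    n_organoids: int

    @property
    def final_npa(self) -> float:
        return float(self.median_npa[-1])

    @property
    def n_frames(self) -> int:
        return len(self.median_npa)


@dataclass
class RelativeSizeTable:
    reference: str
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows.copy()


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display rounding
    of the relative-size table)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def compute_npa(
    track: Track, window: int = 5, condition: str = "", n_frames: int | None = None
) -> NPACurve:
    """Normalize one complete track's areas to its own baseline window mean."""
    if any(e.missing for e in track.entries):
        raise ValueError(
            f"track {track.organoid_id} has missing frames; NPA is defined "
            "only for complete tracks"
        )
    areas = track.areas()
    if n_frames is not None and len(areas) != n_frames:
        raise ValueError(
            f"track {track.organoid_id} spans {len(areas)} frames, expected {n_frames}"
        )
    if window < 1 or window > len(areas):
        raise ValueError("window must lie in [1, n_frames]")
    baseline = float(areas[:window].mean())
    if baseline <= 0:
        raise ValueError("baseline area must be positive")
    return NPACurve(
        organoid_id=track.organoid_id,
        condition=condition,
        baseline_area_um2=baseline,
        npa=areas / baseline,
        window=window,
    )


def condition_median_curve(curves: list[NPACurve]) -> ConditionSummary:
    """Per-frame median NPA across organoids of one condition.

    Even counts use the midpoint of the two central order statistics.
    """
    if not curves:
        raise ValueError("no NPA curves")
    lengths = {len(c.npa) for c in curves}
    if len(lengths) != 1:
        raise ValueError("curves have unequal lengths")
    conditions = {c.condition for c in curves}
    if len(conditions) != 1:
        raise ValueError("curves from multiple conditions")
    stacked = np.vstack([c.npa for c in curves])
    return ConditionSummary(
        condition=conditions.pop(),
        median_npa=np.median(stacked, axis=0),
        n_organoids=len(curves),
    )


def relative_sizes(
    final_npas: dict[str, float],
    reference: str,
    dose_pair: tuple[str, str] | None = None,
) -> RelativeSizeTable:
    """Relative-size table from final median NPA values.

    Each condition's percentage is ``100 * final / final(reference)``,
    rounded half away from zero; ``diff_vs_100`` is the signed size
    difference (negative = reduction, positive = increase). The optional
    ``dose_pair = (high, low)`` adds a direct high-vs-low dose comparison
    row. Percentages are computed from the values as given, at full
    precision.
    """
    if reference not in final_npas:
        raise KeyError(f"reference condition {reference!r} not present")
    ref = final_npas[reference]
    if ref <= 0:
        raise ValueError("reference final NPA must be positive")
    rows = []
    for cond, value in final_npas.items():
        pct = round_half_away(100.0 * value / ref)
        rows.append(
            {
                "condition": cond,
                "final_npa": value,
                "percent_vs_reference": pct,
                "diff_vs_100": pct - 100,
            }
        )
    if dose_pair is not None:
        high, low = dose_pair
        for name in (high, low):
            if name not in final_npas:
                raise KeyError(f"dose condition {name!r} not present")
        pct = round_half_away(100.0 * final_npas[high] / final_npas[low])
        rows.append(
            {
                "condition": f"{high} vs {low}",
                "final_npa": float("nan"),
                "percent_vs_reference": pct,
                "diff_vs_100": pct - 100,
            }
        )
    return RelativeSizeTable(reference=reference, rows=pd.DataFrame(rows))


def relative_size_table(
    summaries: list[ConditionSummary],
    reference: str,
    dose_pair: tuple[str, str] | None = None,
) -> RelativeSizeTable:
    """Relative-size table from condition summaries (see ``relative_sizes``)."""
    return relative_sizes(
        {s.condition: s.final_npa for s in summaries}, reference, dose_pair
    )


def npa_dataframe(curves: list[NPACurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for frame, v in enumerate(c.npa):
            rows.append((c.organoid_id, c.condition, frame, v))
    return pd.DataFrame(rows, columns=["organoid_id", "condition", "frame", "npa"])


def median_curves_dataframe(summaries: list[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for frame, v in enumerate(s.median_npa):
            rows.append((s.condition, frame, v))
    return pd.DataFrame(rows, columns=["condition", "frame", "median_npa"])
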