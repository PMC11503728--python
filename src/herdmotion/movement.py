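"""Scale-invariant displacement and its daily/hourly aggregation.

The displacement between consecutive group points is normalized by the
image diagonal and expressed as a percentage:

    D = 100 * sqrt((x_i - x_{i-1})^2 + (y_i - y_{i-1})^2) / sqrt(H^2 + W^2)

so the same footage analyzed at any rescaling yields identical numbers.
Frames with no detections are gaps; the gap policy decides whether the
adjacent pairs are dropped ("skip", the default — never invents movement)
or spanned ("bridge", with the elapsed time accumulated).  Daily and
hourly summaries assign each pair to the calendar day / hour of its
destination frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime
from typing import Optional, Sequence

import pandas as pd

from .errors import OrderingError, ParameterError
from .geometry import Point2D
from .grouping import GroupPoint

__all__ = [
    "FrameGeometry",
    "Displacement",
    "MissingPair",
    "DisplacementSeries",
    "DailySummary",
    "normalized_distance",
    "displacement_series",
    "aggregate_daily",
    "hourly_profile",
]

GAP_POLICIES = ("skip", "bridge")


@dataclass(frozen=True)
class FrameGeometry:
    """Image width and height in pixels."""

    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ParameterError("frame dimensions must be >= 1")

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)


@dataclass(frozen=True)
class Displacement:
    """Normalized move between two frames with present group points."""

    from_frame: str
    to_frame: str
    d_pct: float  # percentage of the image diagonal
    dt_s: float
    timestamp: datetime  # destination-frame timestamp (day/hour assignment)


@dataclass(frozen=True)
class MissingPair:
    """An adjacent frame pair excluded because one side is a gap."""

    from_frame: str
    to_frame: str
    timestamp: datetime


@dataclass
class DisplacementSeries:
    displacements: list[Displacement]
    missing: list[MissingPair]

    @property
    def total_d(self) -> float:
        return sum(d.d_pct for d in self.displacements)


@dataclass(frozen=True)
class DailySummary:
    day: date
    total_d: float
    n_pairs: int
    n_missing: int

    @property
    def no_data(self) -> bool:
        return self.n_pairs == 0


def normalized_distance(prev: Point2D, curr: Point2D, geom: FrameGeometry) -> float:
    """Euclidean displacement as a percentage of the image diagonal."""
    return 100.0 * math.hypot(curr.x - prev.x, curr.y - prev.y) / geom.diagonal


def displacement_series(
    track: Sequence[GroupPoint],
    geom: FrameGeometry,
    gap_policy: str = "skip",
) -> DisplacementSeries:
    """Per-pair displacements along a chronological group-point track.

    Under "skip", every consecutive pair of frames is considered and pairs
    touching an empty frame are recorded as missing.  Under "bridge",
    consecutive *present* points are paired across any gap, with dt
    accumulated over the spanned interval.
    """
    if gap_policy not in GAP_POLICIES:
        raise ParameterError(
            f"unknown gap policy {gap_policy!r}; expected one of {GAP_POLICIES}"
        )
    for prev, curr in zip(track, track[1:]):
        if curr.timestamp <= prev.timestamp:
            raise OrderingError(
                f"track not chronological at frame {curr.frame_id!r}"
            )

    displacements: list[Displacement] = []
    missing: list[MissingPair] = []
    if gap_policy == "skip":
        for prev, curr in zip(track, track[1:]):
            if prev.point is not None and curr.point is not None:
                displacements.append(
                    Displacement(
                        from_frame=prev.frame_id,
                        to_frame=curr.frame_id,
                        d_pct=normalized_distance(prev.point, curr.point, geom),
                        dt_s=(curr.timestamp - prev.timestamp).total_seconds(),
                        timestamp=curr.timestamp,
                    )
                )
            else:
                missing.append(
                    MissingPair(prev.frame_id, curr.frame_id, curr.timestamp)
                )
    else:  # bridge
        last: Optional[GroupPoint] = None
        for gp in track:
            if gp.point is None:
                continue
            if last is not None:
                displacements.append(
                    Displacement(
                        from_frame=last.frame_id,
                        to_frame=gp.frame_id,
                        d_pct=normalized_distance(last.point, gp.point, geom),
                        dt_s=(gp.timestamp - last.timestamp).total_seconds(),
                        timestamp=gp.timestamp,
                    )
                )
            last = gp
    return DisplacementSeries(displacements=displacements, missing=missing)


def aggregate_daily(series: DisplacementSeries) -> list[DailySummary]:
    """Sum displacements per calendar day of the destination frame.

    A pair crossing midnight belongs to the later day.  Days that appear
    only through missing pairs are reported with total 0 and are
    flagged via ``DailySummary.no_data``.
    """
    per_day: dict[date, dict] = {}
    for d in series.displacements:
        slot = per_day.setdefault(
            d.timestamp.date(), {"total": 0.0, "pairs": 0, "missing": 0}
        )
        slot["total"] += d.d_pct
        slot["pairs"] += 1
    for m in series.missing:
        slot = per_day.setdefault(
            m.timestamp.date(), {"total": 0.0, "pairs": 0, "missing": 0}
        )
        slot["missing"] += 1
    return [
        DailySummary(
            day=day,
            total_d=slot["total"],
            n_pairs=slot["pairs"],
            n_missing=slot["missing"],
        )
        for day, slot in sorted(per_day.items())
    ]


def hourly_profile(
    series: DisplacementSeries, day: Optional[date] = None
) -> pd.DataFrame:
    """24-bin profile of summed displacement and pair counts.

    Bin h collects pairs whose destination timestamp falls in hour h; the
    bins therefore sum exactly to the (daily) total.  Restrict to one
    calendar day with ``day``; otherwise all pairs are pooled.
    """
    totals = [0.0] * 24
    counts = [0] * 24
    for d in series.displacements:
        if day is not None and d.timestamp.date() != day:
            continue
        totals[d.timestamp.hour] += d.d_pct
        counts[d.timestamp.hour] += 1
    return pd.DataFrame(
        {"hour": range(24), "total_d": totals, "n_pairs": counts}
    )


def daily_summary_frame(series: DisplacementSeries) -> pd.DataFrame:
    """Tabular daily view with an observed-hours rate column.

    ``d_per_hour`` divides the day's total by the hours actually covered
    by its pairs (rather than assuming a nominal pair duration), which
    keeps unevenly sampled manifests comparable.
    """
    observed_s: dict[date, float] = {}
    for d in series.displacements:
        observed_s[d.timestamp.date()] = (
            observed_s.get(d.timestamp.date(), 0.0) + d.dt_s
        )
    rows = []
    for s in aggregate_daily(series):
        hours = observed_s.get(s.day, 0.0) / 3600.0
        rows.append(
            {
                "day": s.day.isoformat(),
                "total_d": s.total_d,
                "n_pairs": s.n_pairs,
                "n_missing": s.n_missing,
                "no_data": s.no_data,
                "d_per_hour": s.total_d / hours if hours > 0 else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["day", "total_d", "n_pairs", "n_missing", "no_data", "d_per_hour"],
    )
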