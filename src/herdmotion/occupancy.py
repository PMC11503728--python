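"""Spatial occupancy of group positions: density grid and quadrant counts.

Where the herd spends its time is summarized two ways: a 2D histogram of
group positions over the pen image (with marginal histograms, density
scaled to [0, 1] by the fullest bin) and counts over four equal quadrant
regions, with ratios between two observation periods.

Region convention (printed in every output header so comparisons are
unambiguous): reading order from the top-left of the image —
A = top-left, B = top-right, C = bottom-left, D = bottom-right, with the
half-open rule x >= W/2 (resp. y >= H/2) assigning boundary points to the
right (resp. bottom) regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .movement import FrameGeometry

__all__ = [
    "OccupancyGrid",
    "RegionCounts",
    "density_grid",
    "quadrant_counts",
    "period_compare",
    "REGION_CONVENTION",
]

REGIONS = ("A", "B", "C", "D")
REGION_CONVENTION = (
    "A=top-left B=top-right C=bottom-left D=bottom-right "
    "(x>=W/2 -> right, y>=H/2 -> bottom)"
)


@dataclass
class OccupancyGrid:
    """2D histogram of positions; ``counts[iy, ix]`` row-major image order.

    ``density`` is counts divided by the maximum bin count (0..1); for an
    empty input it is all zeros.  ``prob`` normalizes to sum 1 instead.
    """

    nx: int
    ny: int
    counts: np.ndarray
    x_marginal: np.ndarray
    y_marginal: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())

    @property
    def density(self) -> np.ndarray:
        peak = self.counts.max()
        if peak == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / peak

    @property
    def prob(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


@dataclass(frozen=True)
class RegionCounts:
    a: int
    b: int
    c: int
    d: int
    period: str = ""

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_dict(self) -> dict[str, int]:
        return {"A": self.a, "B": self.b, "C": self.c, "D": self.d}


def _points_xy(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(
        [(p.x, p.y) if hasattr(p, "x") else tuple(p) for p in points],
        dtype=float,
    ).reshape(-1, 2)
    return arr[:, 0], arr[:, 1]


def _clip_to_frame(x, y, geom: FrameGeometry):
    outside = (x < 0) | (x > geom.width) | (y < 0) | (y > geom.height)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} point(s) outside the frame were clipped",
            stacklevel=3,
        )
        x = np.clip(x, 0, geom.width)
        y = np.clip(y, 0, geom.height)
    return x, y


def density_grid(
    points, geom: FrameGeometry, nx: int = 64, ny: int = 29
) -> OccupancyGrid:
    """Histogram positions into an nx-by-ny grid over the frame.

    Bins are half-open [k·W/nx, (k+1)·W/nx) except the last, which is
    closed, so every in-frame point lands in exactly one bin and the
    counts always sum to the number of input points.
    """
    if nx < 1 or ny < 1:
        raise ParameterError("grid bin counts must be >= 1")
    x, y = _points_xy(points)
    if len(x) == 0:
        zero = np.zeros((ny, nx), dtype=int)
        return OccupancyGrid(
            nx=nx,
            ny=ny,
            counts=zero,
            x_marginal=np.zeros(nx, dtype=int),
            y_marginal=np.zeros(ny, dtype=int),
        )
    x, y = _clip_to_frame(x, y, geom)
    counts, _, _ = np.histogram2d(
        x, y, bins=[nx, ny], range=[[0, geom.width], [0, geom.height]]
    )
    counts = counts.T.astype(int)  # (ny, nx), image row-major
    return OccupancyGrid(
        nx=nx,
        ny=ny,
        counts=counts,
        x_marginal=counts.sum(axis=0),
        y_marginal=counts.sum(axis=1),
    )


def quadrant_counts(points, geom: FrameGeometry, period: str = "") -> RegionCounts:
    """Count positions in the four equal quadrants A/B/C/D.

    Identical to a 2-by-2 density grid by construction (cross-checked in
    the test suite): the half-open rule sends x = W/2 to the right and
    y = H/2 to the bottom half.
    """
    x, y = _points_xy(points)
    if len(x) == 0:
        return RegionCounts(0, 0, 0, 0, period=period)
    x, y = _clip_to_frame(x, y, geom)
    right = x >= geom.width / 2.0
    bottom = y >= geom.height / 2.0
    return RegionCounts(
        a=int((~right & ~bottom).sum()),
        b=int((right & ~bottom).sum()),
        c=int((~right & bottom).sum()),
        d=int((right & bottom).sum()),
        period=period,
    )


def period_compare(counts_p1: RegionCounts, counts_p2: RegionCounts) -> pd.DataFrame:
    """Per-region ratio of period-1 to period-2 counts.

    A zero period-2 count yields an undefined ratio (NaN with
    ``defined=False``), never infinity.
    """
    rows = []
    d1, d2 = counts_p1.as_dict(), counts_p2.as_dict()
    for region in REGIONS:
        n1, n2 = d1[region], d2[region]
        defined = n2 > 0
        rows.append(
            {
                "region": region,
                "count_p1": n1,
                "count_p2": n2,
                "ratio": n1 / n2 if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows, columns=["region", "count_p1", "count_p2", "ratio", "defined"])
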