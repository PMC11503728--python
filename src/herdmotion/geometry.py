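"""Polygon geometry, rasterization, and candidate center-point algorithms.

An overhead instance-segmentation detector describes each pig as a closed
contour — an ordered list of (x, y) vertices in pixel coordinates.  Movement
monitoring condenses every contour to a single representative point.  Four
candidate definitions of that point are implemented here:

``centroid_mean``
    Arithmetic mean of the contour vertices.  Cheap, but vertices far from
    the body (e.g. the legs of a lying pig) carry disproportionate weight.
``centroid_least_squares``
    Iterative minimizer of the sum of squared vertex distances.  Its
    analytic minimizer *is* the vertex mean, so it reproduces
    ``centroid_mean`` up to the convergence tolerance; it is kept as an
    explicit comparison algorithm.
``centroid_signed_area``
    Area-weighted polygon centroid from the shoelace formula (triangle-fan
    decomposition).  Insensitive to vertex density, but still reacts to
    small boundary changes via the area weighting.
``centroid_spatial_moment``
    Centroid of the *filled raster mask* of the contour via image spatial
    moments: m_ji = Σ_{x,y} I(x,y)·x^j·y^i and (x̄, ȳ) = (m10/m00,
    m01/m00).  Because every interior pixel carries equal weight, thin
    appendages contribute only their (small) area, making this the most
    stable center under posture changes.  This is the method the monitoring
    pipeline uses by default.

Coordinate convention (used everywhere in this package): origin at the
top-left of the image, x rightward, y downward, pixel centers at integer
coordinates, 0-based.  Rasterization samples pixel *centers* under the
even-odd rule; a pixel whose center lies exactly on the contour counts as
inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConvergenceError,
    EmptyMaskError,
    InvalidGeometryError,
    ParameterError,
)

__all__ = [
    "Point2D",
    "Polygon",
    "RasterMask",
    "SpatialMoments",
    "rasterize_polygon",
    "spatial_moments",
    "centroid_mean",
    "centroid_least_squares",
    "centroid_signed_area",
    "centroid_spatial_moment",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Point2D:
    """A point in pixel coordinates (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_vertex_array(vertices) -> np.ndarray:
    if isinstance(vertices, Polygon):
        return vertices.vertices.copy()
    arr = np.asarray(
        [(v.x, v.y) if isinstance(v, Point2D) else tuple(v) for v in vertices],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidGeometryError("vertices must be a sequence of (x, y) pairs")
    return arr


def _dedup_ring(arr: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices, including the wrap-around pair."""
    if len(arr) == 0:
        return arr
    keep = np.ones(len(arr), dtype=bool)
    keep[1:] = np.any(arr[1:] != arr[:-1], axis=1)
    out = arr[keep]
    while len(out) > 1 and np.all(out[-1] == out[0]):
        out = out[:-1]
    return out


def _shoelace_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y1 - x1 * y))


class Polygon:
    """A closed contour: ordered vertices, last implicitly joined to first.

    The raw vertex list is preserved exactly as given (duplicate vertices
    included — the vertex-mean center intentionally sees them), while
    validity is judged on the ring with consecutive duplicates removed:
    at least three distinct vertices and nonzero signed area.

    Pass ``validate=False`` only in controlled situations (e.g. exercising
    degenerate inputs); downstream operations may then raise.
    """

    __slots__ = ("vertices", "_ring")

    def __init__(self, vertices: Iterable, validate: bool = True):
        arr = _as_vertex_array(vertices)
        self.vertices = arr
        self._ring = _dedup_ring(arr)
        if validate:
            if not np.isfinite(arr).all():
                raise InvalidGeometryError("polygon has non-finite vertices")
            if len(self._ring) < 3:
                raise InvalidGeometryError(
                    f"polygon needs >=3 distinct vertices, got {len(self._ring)}"
                )
            if abs(_shoelace_area(self._ring)) <= 0.0:
                raise InvalidGeometryError("polygon has zero area")

    @property
    def ring(self) -> np.ndarray:
        """Vertices with consecutive duplicates removed (closed implicitly)."""
        return self._ring

    @property
    def signed_area(self) -> float:
        """Shoelace signed area; positive for counter-clockwise order in
        conventional axes (clockwise on screen with y downward)."""
        return _shoelace_area(self._ring)

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the raw vertices."""
        v = self.vertices
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )

    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self.vertices + np.array([dx, dy]), validate=False)

    def __len__(self) -> int:
        return len(self.vertices)

    def __repr__(self) -> str:
        return f"Polygon({len(self.vertices)} vertices, area={self.area:.1f})"


@dataclass
class RasterMask:
    """Binary image grid; ``intensity[y, x]`` in {0, 1}."""

    width: int
    height: int
    intensity: np.ndarray

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ParameterError("mask dimensions must be >= 1")
        self.intensity = np.asarray(self.intensity, dtype=np.uint8)
        if self.intensity.shape != (self.height, self.width):
            raise ParameterError(
                f"intensity shape {self.intensity.shape} != "
                f"(height={self.height}, width={self.width})"
            )
        if not np.isin(self.intensity, (0, 1)).all():
            raise ParameterError("mask values must be 0 or 1")

    def at(self, x: int, y: int) -> int:
        return int(self.intensity[y, x])

    def count(self) -> int:
        return int(self.intensity.sum())


@dataclass(frozen=True)
class SpatialMoments:
    """Raw image moments of a binary mask: m00 (pixel count), m10, m01."""

    m00: float
    m10: float
    m01: float


def _fill_window(
    ring: np.ndarray, x0: int, x1: int, y0: int, y1: int
) -> np.ndarray:
    """Even-odd scanline fill over the pixel centers x0..x1 × y0..y1.

    Returns a bool array of shape (y1-y0+1, x1-x0+1).  A pixel is set iff
    its center is inside the closed polygon under the even-odd rule, or
    lies exactly on an edge (boundary counts as inside).
    """
    w = x1 - x0 + 1
    h = y1 - y0 + 1
    mask = np.zeros((h, w), dtype=bool)

    ax, ay = ring[:, 0], ring[:, 1]
    bx, by = np.roll(ax, -1), np.roll(ay, -1)
    non_horizontal = ay != by

    ys = np.arange(y0, y1 + 1, dtype=float)
    lo = np.minimum(ay, by)
    hi = np.maximum(ay, by)
    # Half-open [lo, hi) rule gives an even crossing count per scanline and
    # counts a vertex shared by an up and a down edge exactly once.
    active = (ys[:, None] >= lo[None, :]) & (ys[:, None] < hi[None, :])
    active &= non_horizontal[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ys[:, None] - ay[None, :]) / (by - ay)[None, :]
    x_cross = ax[None, :] + t * (bx - ax)[None, :]
    x_cross = np.where(active, x_cross, np.inf)
    x_cross.sort(axis=1)
    n_cross = active.sum(axis=1)

    for r in range(h):
        row = x_cross[r]
        for k in range(0, int(n_cross[r]), 2):
            left = math.ceil(row[k] - _EPS) - x0
            right = math.floor(row[k + 1] + _EPS) - x0
            if right < 0 or left >= w:
                continue
            mask[r, max(left, 0) : min(right, w - 1) + 1] = True

    # Boundary pass: pixel centers lying exactly on an edge are inside.
    for i in range(len(ring)):
        dx = bx[i] - ax[i]
        dy = by[i] - ay[i]
        if dx == 0.0 and dy == 0.0:
            continue
        if abs(dx) >= abs(dy):
            xs = np.arange(
                math.ceil(min(ax[i], bx[i]) - _EPS),
                math.floor(max(ax[i], bx[i]) + _EPS) + 1,
            )
            y_line = ay[i] + (xs - ax[i]) * dy / dx
            on = np.abs(y_line - np.rint(y_line)) <= _EPS
            px = xs[on].astype(int)
            py = np.rint(y_line[on]).astype(int)
        else:
            yy = np.arange(
                math.ceil(min(ay[i], by[i]) - _EPS),
                math.floor(max(ay[i], by[i]) + _EPS) + 1,
            )
            x_line = ax[i] + (yy - ay[i]) * dx / dy
            on = np.abs(x_line - np.rint(x_line)) <= _EPS
            px = np.rint(x_line[on]).astype(int)
            py = yy[on].astype(int)
        keep = (px >= x0) & (px <= x1) & (py >= y0) & (py <= y1)
        mask[py[keep] - y0, px[keep] - x0] = True

    return mask


def rasterize_polygon(poly: Polygon, width: int, height: int) -> RasterMask:
    """Fill a polygon onto a ``width`` × ``height`` pixel grid.

    Pixel centers sit at integer coordinates; a pixel is set iff its center
    is inside the closed contour (even-odd rule, boundary inclusive).
    Vertices may lie outside the frame — the mask is clipped to it.
    """
    if width < 1 or height < 1:
        raise ParameterError("frame dimensions must be >= 1")
    if len(poly.ring) < 3 or poly.area <= 0.0:
        raise InvalidGeometryError("cannot rasterize a degenerate polygon")
    filled = _fill_window(poly.ring, 0, width - 1, 0, height - 1)
    return RasterMask(width, height, filled.astype(np.uint8))


def spatial_moments(mask: RasterMask) -> SpatialMoments:
    """Raw moments m00, m10, m01 of a binary mask.

    m_ji = Σ_{x,y} I(x,y) · x^j · y^i.  An all-zero mask yields (0, 0, 0).
    """
    grid = mask.intensity
    col = grid.sum(axis=0, dtype=np.int64)  # per-x pixel counts
    row = grid.sum(axis=1, dtype=np.int64)  # per-y pixel counts
    m00 = float(col.sum())
    m10 = float(np.dot(col, np.arange(mask.width)))
    m01 = float(np.dot(row, np.arange(mask.height)))
    return SpatialMoments(m00=m00, m10=m10, m01=m01)


def centroid_spatial_moment(
    poly: Polygon, frame_width: int, frame_height: int
) -> Point2D:
    """Spatial-moment center (x̄, ȳ) = (m10/m00, m01/m00) of the filled
    contour rasterized inside the frame.

    Only the polygon's bounding window (clipped to the frame) is
    rasterized; moments are offset back to frame coordinates, so the
    result is identical to rasterizing the whole frame.
    """
    if frame_width < 1 or frame_height < 1:
        raise ParameterError("frame dimensions must be >= 1")
    min_x, min_y, max_x, max_y = poly.bounds()
    x0 = max(0, math.ceil(min_x - _EPS))
    x1 = min(frame_width - 1, math.floor(max_x + _EPS))
    y0 = max(0, math.ceil(min_y - _EPS))
    y1 = min(frame_height - 1, math.floor(max_y + _EPS))
    if x0 > x1 or y0 > y1:
        raise EmptyMaskError("contour covers no pixel center inside the frame")
    window = _fill_window(poly.ring, x0, x1, y0, y1)
    m00 = float(window.sum())
    if m00 == 0.0:
        raise EmptyMaskError("contour covers no pixel center inside the frame")
    col = window.sum(axis=0)
    row = window.sum(axis=1)
    m10 = float(np.dot(col, np.arange(x0, x1 + 1)))
    m01 = float(np.dot(row, np.arange(y0, y1 + 1)))
    return Point2D(m10 / m00, m01 / m00)


def centroid_mean(poly: Polygon) -> Point2D:
    """Arithmetic mean of the raw contour vertices.

    Duplicate vertices are deliberately *not* removed: repeated or densely
    annotated stretches of contour (e.g. legs) weigh more, which is exactly
    the behavior this comparison algorithm is meant to exhibit.
    """
    mean = poly.vertices.mean(axis=0)
    return Point2D(float(mean[0]), float(mean[1]))


def centroid_least_squares(
    poly: Polygon, tol: float = 1e-9, max_iter: int = 200
) -> Point2D:
    """Iterative minimizer of Σ_k ‖v_k − c‖² over center candidates c.

    Gradient descent with a contraction factor of 1/2 per step; converges
    to within ``tol`` of the analytic minimizer, which is the vertex mean.
    The iterative route is kept on purpose: it is one of the compared
    center algorithms, not a numerical necessity.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    v = poly.vertices
    n = len(v)
    vertex_sum = v.sum(axis=0)
    c = v[0].astype(float).copy()
    lr = 0.25 / n  # step = lr * grad contracts (c - mean) by exactly 1/2
    for _ in range(max_iter):
        grad = 2.0 * (n * c - vertex_sum)
        step = lr * grad
        c = c - step
        if math.hypot(step[0], step[1]) < 0.5 * tol:
            return Point2D(float(c[0]), float(c[1]))
    raise ConvergenceError(
        f"least-squares center did not converge in {max_iter} iterations",
        last_iterate=Point2D(float(c[0]), float(c[1])),
    )


def centroid_signed_area(poly: Polygon) -> Point2D:
    """Area-weighted polygon centroid via the shoelace formula.

    With A = ½ Σ (x_k·y_{k+1} − x_{k+1}·y_k) over the closed ring,
    Cx = (1/6A) Σ (x_k + x_{k+1})(x_k·y_{k+1} − x_{k+1}·y_k) and Cy
    analogously.  The result is independent of vertex orientation.
    """
    ring = poly.ring
    if len(ring) < 3:
        raise InvalidGeometryError("polygon needs >=3 distinct vertices")
    x, y = ring[:, 0], ring[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * float(cross.sum())
    if a == 0.0:
        raise InvalidGeometryError("polygon has zero area")
    cx = float(np.sum((x + x1) * cross)) / (6.0 * a)
    cy = float(np.sum((y + y1) * cross)) / (6.0 * a)
    return Point2D(cx, cy)


#: Registry of the four center-point algorithms, keyed by the names the
#: pipeline configuration uses.  Each takes (polygon, frame_width,
#: frame_height) and returns a Point2D; the purely polygonal algorithms
#: ignore the frame size.
CENTER_METHODS = {
    "mean": lambda poly, w, h: centroid_mean(poly),
    "least_squares": lambda poly, w, h: centroid_least_squares(poly),
    "signed_area": lambda poly, w, h: centroid_signed_area(poly),
    "spatial_moment": centroid_spatial_moment,
}


def compute_center(poly: Polygon, method: str, frame_width: int, frame_height: int) -> Point2D:
    """Dispatch to one of the registered center algorithms by name."""
    try:
        fn = CENTER_METHODS[method]
    except KeyError:
        raise ParameterError(
            f"unknown center method {method!r}; expected one of "
            f"{sorted(CENTER_METHODS)}"
        ) from None
    return fn(poly, frame_width, frame_height)
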