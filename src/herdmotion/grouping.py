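"""Condensing per-pig centers into one group position per frame.

A herd of group-housed pigs is summarized each frame by a single point:
the per-pig centers are clustered bottom-up (agglomerative clustering)
and the cluster representative is the arithmetic mean of its members.
With the default of one cluster the group point is exactly the mean of
all centers; the clustering machinery exists so that the operator is
configurable (k > 1, alternative algorithms) and benchmarkable.

The agglomerative clusterer is implemented here with Lance–Williams
updates and fully deterministic tie-breaking; the alternative algorithms
available to the runtime benchmark (k-means++, DBSCAN, mean shift,
Gaussian mixture) are delegated to scikit-learn.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import Point2D

__all__ = [
    "PigCenter",
    "GroupPoint",
    "agglomerative_cluster",
    "group_center",
    "benchmark_clusterers",
    "CLUSTER_ALGORITHMS",
]

LINKAGES = ("single", "complete", "average", "ward")


@dataclass(frozen=True)
class PigCenter:
    """One pig's representative point in one frame."""

    frame_id: str
    pig_index: int
    point: Point2D
    confidence: Optional[float] = None


@dataclass(frozen=True)
class GroupPoint:
    """The single per-frame position of the herd; absent on empty frames."""

    frame_id: str
    timestamp: datetime
    point: Optional[Point2D]
    n_pigs: int

    def __post_init__(self):
        if (self.point is None) != (self.n_pigs == 0):
            raise ParameterError("point must be absent iff n_pigs == 0")


def _points_array(points) -> np.ndarray:
    return np.asarray(
        [(p.x, p.y) if isinstance(p, Point2D) else tuple(p) for p in points],
        dtype=float,
    ).reshape(-1, 2)


def agglomerative_cluster(
    points: Sequence, n_clusters: int, linkage: str = "ward"
) -> np.ndarray:
    """Bottom-up hierarchical clustering under Euclidean distance.

    Successively merges the closest pair of clusters until ``n_clusters``
    remain.  Inter-cluster dissimilarity follows the chosen linkage
    (single / complete / average via Lance–Williams updates; ward as the
    within-cluster sum-of-squares increase).  Ties are broken by the pair
    with the lowest cluster indices, where a cluster's index is the
    smallest original point index it contains, so the result is
    deterministic given the input order.

    Returns one integer label per point; labels number the final clusters
    0..k-1 in order of their smallest member index.
    """
    pts = _points_array(points)
    n = len(pts)
    if n == 0:
        raise ParameterError("cannot cluster an empty point list")
    if not 1 <= n_clusters <= n:
        raise ParameterError(
            f"n_clusters must be in [1, {n}], got {n_clusters}"
        )
    if linkage not in LINKAGES:
        raise ParameterError(
            f"unknown linkage {linkage!r}; expected one of {LINKAGES}"
        )

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    if linkage == "ward":
        # Singleton merge cost = Delta SSE = ||xi - xj||^2 / 2.
        dmat = dist**2 / 2.0
    else:
        dmat = dist.copy()
    np.fill_diagonal(dmat, np.inf)

    active = list(range(n))  # cluster ids == smallest original member index
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    centroids = {i: pts[i].copy() for i in range(n)}

    while len(active) > n_clusters:
        best = (np.inf, -1, -1)
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                cand = (dmat[i, j], i, j)
                if cand < best:
                    best = cand
        _, i, j = best
        si, sj = sizes[i], sizes[j]
        new_centroid = (centroids[i] * si + centroids[j] * sj) / (si + sj)
        for k in active:
            if k in (i, j):
                continue
            if linkage == "single":
                d_new = min(dmat[i, k], dmat[j, k])
            elif linkage == "complete":
                d_new = max(dmat[i, k], dmat[j, k])
            elif linkage == "average":
                d_new = (si * dmat[i, k] + sj * dmat[j, k]) / (si + sj)
            else:  # ward: recompute Delta SSE from centroids and sizes
                sk = sizes[k]
                gap = new_centroid - centroids[k]
                d_new = ((si + sj) * sk / (si + sj + sk)) * float(gap @ gap)
            dmat[i, k] = dmat[k, i] = d_new
        members[i].extend(members[j])
        sizes[i] += sizes[j]
        centroids[i] = new_centroid
        active.remove(j)
        del members[j], sizes[j], centroids[j]

    labels = np.empty(n, dtype=int)
    for label, cid in enumerate(sorted(active)):
        labels[members[cid]] = label
    return labels


# --- alternative clusterers (benchmark harness; delegated to scikit-learn) ---


def _labels_kmeans(pts: np.ndarray, k: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    k = min(k, len(pts))
    return KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=0).fit_predict(pts)


def _labels_dbscan(pts: np.ndarray, k: int) -> np.ndarray:
    from sklearn.cluster import DBSCAN

    # eps scaled to the data spread; min_samples=1 so no point is noise
    # and the count conservation invariant holds.
    span = float(np.ptp(pts, axis=0).max()) or 1.0
    return DBSCAN(eps=span / 4.0 + 1e-9, min_samples=1).fit_predict(pts)


def _labels_meanshift(pts: np.ndarray, k: int) -> np.ndarray:
    from sklearn.cluster import MeanShift

    if len(pts) == 1:
        return np.zeros(1, dtype=int)
    return MeanShift().fit_predict(pts)


def _labels_gmm(pts: np.ndarray, k: int) -> np.ndarray:
    from sklearn.mixture import GaussianMixture

    if len(pts) == 1:
        return np.zeros(1, dtype=int)
    k = min(k, len(pts))
    return GaussianMixture(n_components=k, random_state=0).fit_predict(pts)


CLUSTER_ALGORITHMS = {
    "agglomerative": lambda pts, k: agglomerative_cluster(pts, min(k, len(pts))),
    "kmeans++": _labels_kmeans,
    "dbscan": _labels_dbscan,
    "meanshift": _labels_meanshift,
    "gmm": _labels_gmm,
}


def _cluster_labels(pts: np.ndarray, method: str, n_clusters: int) -> np.ndarray:
    try:
        fn = CLUSTER_ALGORITHMS[method]
    except KeyError:
        raise ParameterError(
            f"unknown clusterer {method!r}; expected one of "
            f"{sorted(CLUSTER_ALGORITHMS)}"
        ) from None
    return np.asarray(fn(pts, n_clusters))


def group_center(
    centers: Sequence[PigCenter],
    timestamp: datetime,
    method: str = "agglomerative",
    n_clusters: int = 1,
    frame_id: Optional[str] = None,
    confidence_weighted: bool = False,
) -> GroupPoint:
    """Reduce the frame's pig centers to a single group point.

    With ``n_clusters=1`` (the default) the group point is exactly the
    arithmetic mean of the member points — clustering adds nothing at
    k = 1, which is asserted by the test suite and documented as such.
    With ``n_clusters > 1`` the group point is the mean of the per-cluster
    means (an extension; all clusters contribute equally regardless of
    size).  An empty frame yields an absent point (a gap marker).
    """
    if method not in CLUSTER_ALGORITHMS:
        raise ParameterError(
            f"unknown clusterer {method!r}; expected one of "
            f"{sorted(CLUSTER_ALGORITHMS)}"
        )
    if frame_id is None:
        frame_id = centers[0].frame_id if centers else ""
    if not centers:
        return GroupPoint(frame_id=frame_id, timestamp=timestamp, point=None, n_pigs=0)

    pts = _points_array([c.point for c in centers])
    if confidence_weighted:
        w = np.array(
            [c.confidence if c.confidence is not None else 1.0 for c in centers]
        )
    else:
        w = np.ones(len(centers))

    if n_clusters <= 1 or len(pts) == 1:
        mean = (pts * w[:, None]).sum(axis=0) / w.sum()
    else:
        labels = _cluster_labels(pts, method, n_clusters)
        cluster_means = []
        for label in np.unique(labels):
            sel = labels == label
            cluster_means.append(
                (pts[sel] * w[sel, None]).sum(axis=0) / w[sel].sum()
            )
        mean = np.mean(cluster_means, axis=0)
    return GroupPoint(
        frame_id=frame_id,
        timestamp=timestamp,
        point=Point2D(float(mean[0]), float(mean[1])),
        n_pigs=len(centers),
    )


def benchmark_clusterers(
    frames: Sequence[Sequence],
    algorithms: Sequence[str],
    repetitions: int = 30,
    n_clusters: int = 1,
) -> pd.DataFrame:
    """Time each clusterer on each frame's point set.

    Every algorithm processes every frame ``repetitions`` times.  The
    returned table has one row per (algorithm, frame) carrying the median
    per-frame runtime across repetitions, plus one ``frame="total"`` row
    per algorithm with the whole-sequence runtime averaged over
    repetitions.  No winner is asserted — runtimes are hardware-dependent.
    """
    if not algorithms:
        raise ParameterError("algorithm list must not be empty")
    for algo in algorithms:
        if algo not in CLUSTER_ALGORITHMS:
            raise ParameterError(f"unknown clusterer {algo!r}")
    if repetitions < 1:
        raise ParameterError("repetitions must be >= 1")

    frame_arrays = [_points_array(f) for f in frames]
    rows = []
    for algo in algorithms:
        per_frame = np.empty((repetitions, len(frame_arrays)))
        for rep in range(repetitions):
            for fi, pts in enumerate(frame_arrays):
                t0 = time.perf_counter()
                _cluster_labels(pts, algo, n_clusters)
                per_frame[rep, fi] = time.perf_counter() - t0
        for fi in range(len(frame_arrays)):
            rows.append(
                {
                    "algorithm": algo,
                    "frame": str(fi),
                    "runtime_s": float(np.median(per_frame[:, fi])),
                }
            )
        rows.append(
            {
                "algorithm": algo,
                "frame": "total",
                "runtime_s": float(per_frame.sum(axis=1).mean()),
            }
        )
    return pd.DataFrame(rows, columns=["algorithm", "frame", "runtime_s"])
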