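"""Synthetic pig scenes with ground truth for every pipeline stage.

The generator emulates what an overhead segmentation detector would emit
for a small pen of group-housed pigs: per-frame pig-shaped contours of
30-50 vertices, three postures (lying / sitting / standing), a latent
group trajectory alternating rest and move phases with a diurnal
activity schedule, frames sampled at a fixed interval.  Everything is
driven by one seed, and the latent trajectory plus per-pig true centers
are retained so recovery at any stage can be checked exactly.

Shapes are star-shaped radius-modulated ellipses (aspect about 2.5:1).
The lying posture adds a few thin radial "leg" spikes on one body side;
these lobes are parametric rather than anatomical — their purpose is to
make the vertex-mean center visibly worse than the raster-moment center,
the adversarial case that separates the centroid algorithms.

Pig-to-pig contact and occlusion are not simulated: these fixtures test
the post-detection arithmetic, not the detector.  An optional dropout
probability deletes detections at random to exercise the gap policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .geometry import Point2D, Polygon
from .labels import FrameManifest, ManifestEntry, write_manifest_csv
from .movement import FrameGeometry, normalized_distance

__all__ = [
    "PenConfig",
    "BehaviorState",
    "GroundTruth",
    "POSES",
    "generate_pig_polygon",
    "default_activity_schedule",
    "simulate_group_walk",
    "write_scene",
]

POSES = ("lying", "sitting", "standing")

#: Posture mix per behavior state: resting pigs mostly lie, moving pigs
#: mostly stand.
_POSE_PROBS = {
    "rest": {"lying": 0.70, "sitting": 0.20, "standing": 0.10},
    "move": {"lying": 0.10, "sitting": 0.15, "standing": 0.75},
}


@dataclass(frozen=True)
class PenConfig:
    """Scene parameters.

    Defaults describe the study conditions this generator emulates: a
    3632 x 1632 px overhead view of a pen with 7 pigs, one frame every
    300 s.  ``body_length_px`` (450) is a plausible apparent body length
    for 100-120-day pigs under a wide-FOV top-down camera at this
    resolution.  ``dispersion_frac`` is the per-pig Gaussian scatter
    around the latent group point as a fraction of the image diagonal.
    """

    width: int = 3632
    height: int = 1632
    n_pigs: int = 7
    interval_s: float = 300.0
    n_frames: int = 288
    seed: int = 0
    start_time: datetime = datetime(2023, 5, 13, 0, 0, 0)
    body_length_px: float = 450.0
    dispersion_frac: float = 0.01
    dropout: float = 0.0

    def __post_init__(self):
        if min(self.width, self.height, self.n_pigs, self.n_frames) < 1:
            raise ParameterError("pen dimensions, pig and frame counts must be >= 1")
        if self.interval_s <= 0 or self.body_length_px <= 0:
            raise ParameterError("interval and body length must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must be in [0, 1)")

    @property
    def geometry(self) -> FrameGeometry:
        return FrameGeometry(self.width, self.height)

    @property
    def diagonal(self) -> float:
        return self.geometry.diagonal


@dataclass(frozen=True)
class BehaviorState:
    """Two-state (rest/move) per-frame Markov walk parameters.

    Step scales are fractions of the image diagonal.  During a move
    frame the latent point travels ``move_step_frac`` x diagonal
    (uniformly dithered by +/-20% and scaled by the hourly activity
    multiplier) in a random direction; during rest it only jitters by a
    small Gaussian step (collective shuffling of the resting herd).  The
    defaults are set so that, with the default diurnal schedule, the
    expected daily summed displacement of the latent trajectory lands
    near what a 5-minute cadence yields for real group-housed pigs
    (on the order of 1000% of the diagonal per day).
    """

    p_rest_to_move: float = 0.25
    p_move_to_rest: float = 0.20
    move_step_frac: float = 0.055
    rest_jitter_frac: float = 0.002

    def __post_init__(self):
        for p in (self.p_rest_to_move, self.p_move_to_rest):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("transition probabilities must be in [0, 1]")
        if self.move_step_frac < 0 or self.rest_jitter_frac < 0:
            raise ParameterError("step scales must be >= 0")


def default_activity_schedule(
    peak_hours: tuple[int, int] = (9, 21), width_h: float = 0.9
) -> np.ndarray:
    """24 hourly activity multipliers.

    The multiplier scales both the rest-to-move hazard and the move step
    length: at an activity peak pigs both start moving more often and
    cover more ground while moving.  Gaussian bumps at the two peak
    hours over a low base produce the characteristic twin daily activity
    peaks (morning and evening) of diurnal pig activity.
    """
    hours = np.arange(24, dtype=float)
    sched = np.full(24, 0.25)
    for peak in peak_hours:
        delta = np.minimum(np.abs(hours - peak), 24 - np.abs(hours - peak))
        sched += 3.2 * np.exp(-(delta**2) / (2 * width_h**2))
    return sched


@dataclass
class GroundTruth:
    """Latent trajectory and per-pig truth for a simulated scene."""

    config: PenConfig
    frame_ids: list[str]
    timestamps: list[datetime]
    latent: np.ndarray  # (n_frames, 2) group trajectory
    states: list[str]  # "rest"/"move" per frame
    pig_centers: np.ndarray  # (n_frames, n_pigs, 2) true polygon placement
    poses: list[list[str]]
    polygons: list[list[Polygon]]
    detected: np.ndarray  # (n_frames, n_pigs) bool, False = dropped out
    schedule: Optional[np.ndarray] = None

    def latent_points(self) -> list[Point2D]:
        return [Point2D(float(x), float(y)) for x, y in self.latent]

    def daily_totals(self) -> dict[date, float]:
        """True summed normalized displacement per calendar day.

        Consecutive latent points form pairs assigned to the day of the
        destination frame — the same convention the pipeline uses.
        """
        geom = self.config.geometry
        totals: dict[date, float] = {}
        pts = self.latent_points()
        for i in range(1, len(pts)):
            day = self.timestamps[i].date()
            totals[day] = totals.get(day, 0.0) + normalized_distance(
                pts[i - 1], pts[i], geom
            )
        return totals

    def hourly_totals(self) -> np.ndarray:
        """True summed displacement per destination hour, pooled over days."""
        geom = self.config.geometry
        bins = np.zeros(24)
        pts = self.latent_points()
        for i in range(1, len(pts)):
            bins[self.timestamps[i].hour] += normalized_distance(
                pts[i - 1], pts[i], geom
            )
        return bins


def generate_pig_polygon(
    center: Point2D,
    pose: str,
    body_length: float,
    heading: float,
    rng: np.random.Generator,
) -> Polygon:
    """One pig-shaped closed contour of 30-50 vertices.

    The body is an ellipse of aspect ~2.5:1 with mild low-order radial
    noise, sampled at slightly jittered angles (a radius function of the
    polar angle: star-shaped, hence never self-intersecting).  Poses:
    standing = smooth ellipse; sitting = ellipse with one flattened
    (rear) end; lying = ellipse plus 2-4 narrow leg spikes on one side.
    Each spike is one vertex pushed radially outward between two flanking
    vertices at body radius a small angle away, so the lobe's area stays
    well under 5% of the body while its tip vertex pulls the vertex-mean
    center hard.  Deterministic given the rng state.
    """
    if pose not in POSES:
        raise ParameterError(f"unknown pose {pose!r}; expected one of {POSES}")
    if body_length <= 0:
        raise ParameterError("body_length must be > 0")

    a = body_length / 2.0
    b = a / 2.5
    phase = rng.uniform(0, 2 * math.pi)

    def base_radius(ang):
        ellipse = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
        return ellipse * (1.0 + 0.03 * np.sin(2 * ang + phase))

    n_legs = int(rng.integers(2, 5)) if pose == "lying" else 0
    # each leg adds 3 vertices; keep the total within the 30-50 band
    n = (
        int(rng.integers(30, 51 - 3 * n_legs))
        if pose == "lying"
        else int(rng.integers(36, 51))
    )
    spacing = 2 * math.pi / n
    theta = (np.arange(n) + 0.5) * spacing
    theta = theta + rng.uniform(-0.25, 0.25, n) * spacing
    radius = base_radius(theta)

    if pose == "sitting":
        # blunt rear end on the -x side
        radius = radius * (1.0 - 0.30 * np.clip(-np.cos(theta), 0.0, 1.0))
    elif pose == "lying":
        # legs on one lateral side: each leg is a thin radial spike of
        # angular half-width delta flanked by body-radius vertices
        delta = 0.02
        window = (0.45, 2.70)
        slots = np.linspace(window[0], window[1], n_legs + 1)
        for k in range(n_legs):
            phi = rng.uniform(slots[k] + 2 * delta, slots[k + 1] - 2 * delta)
            r_phi = float(base_radius(np.array([phi]))[0])
            reach = r_phi * (1.0 + rng.uniform(0.9, 1.3))
            theta = np.append(theta, [phi - delta, phi, phi + delta])
            radius = np.append(radius, [r_phi, reach, r_phi])
        order = np.argsort(theta)
        theta, radius = theta[order], radius[order]

    local = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    cos_h, sin_h = math.cos(heading), math.sin(heading)
    rot = np.array([[cos_h, -sin_h], [sin_h, cos_h]])
    verts = local @ rot.T + np.array([center.x, center.y])
    return Polygon(verts)


def _sample_pose(state: str, rng: np.random.Generator) -> str:
    probs = _POSE_PROBS[state]
    return str(rng.choice(POSES, p=[probs[p] for p in POSES]))


def simulate_group_walk(
    config: PenConfig,
    behavior: Optional[BehaviorState] = None,
    activity_schedule: Optional[Sequence[float]] = None,
) -> GroundTruth:
    """Simulate the latent group trajectory and the per-pig scene.

    The latent point follows a rest/move two-state walk with reflective
    pen boundaries (kept at a margin so every pig contour stays inside
    the frame).  Each pig sits at the latent point plus Gaussian scatter
    of ``dispersion_frac`` x diagonal.  The herd formation is
    *persistent*: while resting, each pig's offset, posture, heading and
    contour shape are frozen and the whole herd rigidly follows the
    latent jitter (a resting herd does not re-scatter every frame);
    offsets and shapes are redrawn on every move frame, when pigs
    actually rearrange.  ``activity_schedule`` (24 multipliers, see
    ``default_activity_schedule``) scales the rest-to-move hazard and
    the move step length by hour of day.
    """
    behavior = behavior or BehaviorState()
    if activity_schedule is not None:
        activity_schedule = np.asarray(activity_schedule, dtype=float)
        if activity_schedule.shape != (24,):
            raise ParameterError("activity_schedule must have 24 entries")
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    diag = config.diagonal

    # margin keeps the whole contour (body + leg spikes) inside the pen
    margin = 0.75 * config.body_length_px
    lo = np.array([margin, margin])
    hi = np.array([config.width - margin, config.height - margin])
    if (hi <= lo).any():
        raise ParameterError("pen too small for the configured body length")

    pos = rng.uniform(lo, hi)
    state = "rest"
    frame_ids, timestamps, states = [], [], []
    latent = np.empty((config.n_frames, 2))
    pig_centers = np.empty((config.n_frames, config.n_pigs, 2))
    poses: list[list[str]] = []
    polygons: list[list[Polygon]] = []
    detected = np.ones((config.n_frames, config.n_pigs), dtype=bool)

    # persistent herd formation, regenerated on move frames
    offsets = np.zeros((config.n_pigs, 2))
    local_shapes: list[Optional[np.ndarray]] = [None] * config.n_pigs
    pig_poses = ["lying"] * config.n_pigs

    for f in range(config.n_frames):
        ts = config.start_time + timedelta(seconds=f * config.interval_s)
        mult = (
            float(activity_schedule[ts.hour]) if activity_schedule is not None else 1.0
        )
        if state == "rest":
            if rng.random() < min(behavior.p_rest_to_move * mult, 0.95):
                state = "move"
        else:
            if rng.random() < behavior.p_move_to_rest:
                state = "rest"
        if state == "move":
            length = behavior.move_step_frac * mult * diag * rng.uniform(0.8, 1.2)
            angle = rng.uniform(0, 2 * math.pi)
            step = np.array([length * math.cos(angle), length * math.sin(angle)])
        else:
            step = rng.normal(0.0, behavior.rest_jitter_frac * diag, 2)
        pos = pos + step
        # reflective boundaries
        for k in range(2):
            span = hi[k] - lo[k]
            t = (pos[k] - lo[k]) % (2 * span)
            pos[k] = lo[k] + (t if t <= span else 2 * span - t)

        latent[f] = pos
        frame_ids.append(f"frame_{f:06d}")
        timestamps.append(ts)
        states.append(state)

        rearrange = state == "move" or f == 0
        frame_poses, frame_polys = [], []
        for p in range(config.n_pigs):
            if rearrange:
                offsets[p] = rng.normal(0.0, config.dispersion_frac * diag, 2)
                pig_poses[p] = _sample_pose(state, rng)
            c = np.clip(pos + offsets[p], lo, hi)
            pig_centers[f, p] = c
            if rearrange:
                poly = generate_pig_polygon(
                    Point2D(float(c[0]), float(c[1])),
                    pig_poses[p],
                    config.body_length_px,
                    heading=float(rng.uniform(0, 2 * math.pi)),
                    rng=rng,
                )
                local_shapes[p] = poly.vertices - c
            else:
                poly = Polygon(local_shapes[p] + c, validate=False)
            frame_poses.append(pig_poses[p])
            frame_polys.append(poly)
            if config.dropout > 0 and rng.random() < config.dropout:
                detected[f, p] = False
        poses.append(frame_poses)
        polygons.append(frame_polys)

    return GroundTruth(
        config=config,
        frame_ids=frame_ids,
        timestamps=timestamps,
        latent=latent,
        states=states,
        pig_centers=pig_centers,
        poses=poses,
        polygons=polygons,
        detected=detected,
        schedule=None if activity_schedule is None else np.asarray(activity_schedule),
    )


def write_scene(truth: GroundTruth, out_dir: str | Path) -> FrameManifest:
    """Write label files, a manifest CSV and ground-truth CSVs.

    Layout: ``labels/<frame_id>.txt`` (YOLO segmentation dialect, class 0,
    normalized coordinates at 6 decimals, no confidence column),
    ``manifest.csv``, ``ground_truth.csv`` (latent trajectory) and
    ``ground_truth_daily.csv``.  Returns the manifest.
    """
    out_dir = Path(out_dir).resolve()
    labels_dir = out_dir / "labels"
    labels_dir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config

    entries = []
    for f, frame_id in enumerate(truth.frame_ids):
        label_path = labels_dir / f"{frame_id}.txt"
        lines = []
        for p, poly in enumerate(truth.polygons[f]):
            if not truth.detected[f, p]:
                continue
            coords = np.clip(
                poly.vertices / np.array([cfg.width, cfg.height]), 0.0, 1.0
            )
            flat = " ".join(f"{v:.6f}" for v in coords.ravel())
            lines.append(f"0 {flat}")
        label_path.write_text("\n".join(lines) + ("\n" if lines else ""))
        entries.append(
            ManifestEntry(
                frame_id=frame_id,
                timestamp=truth.timestamps[f],
                label_path=label_path,
                width=cfg.width,
                height=cfg.height,
            )
        )
    manifest = FrameManifest(entries)
    write_manifest_csv(manifest, out_dir / "manifest.csv")

    with (out_dir / "ground_truth.csv").open("w") as fh:
        fh.write("frame_id,timestamp,latent_x,latent_y,state\n")
        for f, frame_id in enumerate(truth.frame_ids):
            fh.write(
                f"{frame_id},{truth.timestamps[f].isoformat(sep=' ')},"
                f"{truth.latent[f, 0]:.6f},{truth.latent[f, 1]:.6f},"
                f"{truth.states[f]}\n"
            )
    with (out_dir / "ground_truth_daily.csv").open("w") as fh:
        fh.write("day,total_d\n")
        for day, total in sorted(truth.daily_totals().items()):
            fh.write(f"{day.isoformat()},{total:.6f}\n")
    return manifest
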