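"""End-to-end workflow: ingest -> centers -> group point -> distance -> analytics.

``run_pipeline`` executes the whole monitoring chain on a frame manifest
and writes every artifact as CSV; ``make_report`` renders the standard
figures (occupancy heatmap with marginals, daily distance bars, hourly
profiles) from those artifacts.  Both are deterministic given the
configuration and inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import HerdmotionError, ParameterError, ReportError
from .geometry import CENTER_METHODS, Point2D, compute_center
from .grouping import CLUSTER_ALGORITHMS, GroupPoint, PigCenter, group_center
from .labels import (
    FrameManifest,
    iter_frames,
    load_manifest,
    read_track_csv,
    write_track_csv,
)
from .movement import (
    DisplacementSeries,
    FrameGeometry,
    GAP_POLICIES,
    aggregate_daily,
    daily_summary_frame,
    displacement_series,
    hourly_profile,
)
from .occupancy import (
    REGION_CONVENTION,
    density_grid,
    period_compare,
    quadrant_counts,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: Path
    out_dir: Path
    center_method: str = "spatial_moment"
    clusterer: str = "agglomerative"
    n_clusters: int = 1
    gap_policy: str = "skip"
    geometry: Optional[FrameGeometry] = None  # default: taken from the manifest
    split_date: Optional[date] = None
    min_confidence: float = 0.0
    has_confidence: Optional[bool] = None
    confidence_weighted: bool = False
    grid_nx: int = 64
    grid_ny: int = 29
    seed: int = 0

    def validate(self) -> None:
        """Reject invalid enumerations before any I/O happens."""
        if self.center_method not in CENTER_METHODS:
            raise ParameterError(
                f"unknown center method {self.center_method!r}; expected one "
                f"of {sorted(CENTER_METHODS)}"
            )
        if self.clusterer not in CLUSTER_ALGORITHMS:
            raise ParameterError(f"unknown clusterer {self.clusterer!r}")
        if self.gap_policy not in GAP_POLICIES:
            raise ParameterError(f"unknown gap policy {self.gap_policy!r}")
        if self.n_clusters < 1:
            raise ParameterError("n_clusters must be >= 1")
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ParameterError("occupancy grid bin counts must be >= 1")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ParameterError("min_confidence must be in [0, 1]")


@dataclass
class PipelineResult:
    config: PipelineConfig
    track: list[GroupPoint]
    series: DisplacementSeries
    artifacts: dict[str, Path] = field(default_factory=dict)


def _echo_config(config: PipelineConfig, out_dir: Path) -> Path:
    payload = {
        "manifest": str(config.manifest),
        "out_dir": str(config.out_dir),
        "center_method": config.center_method,
        "clusterer": config.clusterer,
        "n_clusters": config.n_clusters,
        "gap_policy": config.gap_policy,
        "geometry": None
        if config.geometry is None
        else [config.geometry.width, config.geometry.height],
        "split_date": None if config.split_date is None else config.split_date.isoformat(),
        "min_confidence": config.min_confidence,
        "grid": [config.grid_nx, config.grid_ny],
        "seed": config.seed,
        "region_convention": REGION_CONVENTION,
    }
    path = out_dir / "config.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def compute_track(
    manifest: FrameManifest, config: PipelineConfig
) -> tuple[list[GroupPoint], FrameGeometry]:
    """Per-frame group points from the manifest's label files."""
    track: list[GroupPoint] = []
    geom = config.geometry
    for record in iter_frames(
        manifest,
        min_confidence=config.min_confidence,
        has_confidence=config.has_confidence,
    ):
        if geom is None:
            geom = FrameGeometry(record.image_width, record.image_height)
        centers = []
        for idx, (poly, _class_id, conf) in enumerate(record.instances):
            try:
                point = compute_center(
                    poly, config.center_method, record.image_width, record.image_height
                )
            except HerdmotionError as exc:
                raise type(exc)(
                    f"[centers] frame {record.frame_id!r}, instance {idx}: {exc}"
                ) from exc
            centers.append(
                PigCenter(
                    frame_id=record.frame_id,
                    pig_index=idx,
                    point=point,
                    confidence=conf,
                )
            )
        track.append(
            group_center(
                centers,
                timestamp=record.timestamp,
                method=config.clusterer,
                n_clusters=config.n_clusters,
                frame_id=record.frame_id,
                confidence_weighted=config.confidence_weighted,
            )
        )
    if geom is None:
        raise ParameterError("empty manifest: no frames to process")
    return track, geom


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run ingest -> centers -> group point -> displacement -> analytics.

    Writes track.csv, displacement.csv, daily.csv, hourly.csv, the
    occupancy grid/marginals/region CSVs (split into two periods when a
    split date is configured, with a per-region ratio table) and a config
    echo for provenance.  Deterministic given config + inputs.
    """
    config.validate()
    manifest = load_manifest(config.manifest)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    track, geom = compute_track(manifest, config)
    series = displacement_series(track, geom, gap_policy=config.gap_policy)
    log.info(
        "pipeline: %d frames, %d displacement pairs, %d missing pairs",
        len(track),
        len(series.displacements),
        len(series.missing),
    )

    artifacts: dict[str, Path] = {"config": _echo_config(config, out_dir)}

    d_by_dest = {d.to_frame: d.d_pct for d in series.displacements}
    track_rows = [
        (
            gp.frame_id,
            gp.timestamp,
            None if gp.point is None else gp.point.x,
            None if gp.point is None else gp.point.y,
            gp.n_pigs,
            d_by_dest.get(gp.frame_id),
        )
        for gp in track
    ]
    artifacts["track"] = out_dir / "track.csv"
    write_track_csv(track_rows, artifacts["track"])

    disp_df = pd.DataFrame(
        [
            {
                "from_frame": d.from_frame,
                "to_frame": d.to_frame,
                "timestamp": d.timestamp.isoformat(sep=" "),
                "d_pct": round(d.d_pct, 6),
                "dt_s": d.dt_s,
            }
            for d in series.displacements
        ],
        columns=["from_frame", "to_frame", "timestamp", "d_pct", "dt_s"],
    )
    artifacts["displacement"] = out_dir / "displacement.csv"
    disp_df.to_csv(artifacts["displacement"], index=False)

    daily_df = daily_summary_frame(series)
    artifacts["daily"] = out_dir / "daily.csv"
    daily_df.to_csv(artifacts["daily"], index=False)

    hourly_frames = []
    for summary in aggregate_daily(series):
        hp = hourly_profile(series, day=summary.day)
        hp.insert(0, "day", summary.day.isoformat())
        hourly_frames.append(hp)
    hourly_df = (
        pd.concat(hourly_frames, ignore_index=True)
        if hourly_frames
        else pd.DataFrame(columns=["day", "hour", "total_d", "n_pairs"])
    )
    artifacts["hourly"] = out_dir / "hourly.csv"
    hourly_df.to_csv(artifacts["hourly"], index=False)

    points = [gp.point for gp in track if gp.point is not None]
    grid = density_grid(points, geom, nx=config.grid_nx, ny=config.grid_ny)
    artifacts["grid"] = out_dir / "occupancy_grid.csv"
    np.savetxt(
        artifacts["grid"],
        grid.counts,
        fmt="%d",
        delimiter=",",
        header=f"occupancy counts, rows=y bins (ny={grid.ny}), cols=x bins (nx={grid.nx})",
    )
    artifacts["marginals"] = out_dir / "occupancy_marginals.csv"
    with artifacts["marginals"].open("w") as fh:
        fh.write("axis,bin,count\n")
        for i, c in enumerate(grid.x_marginal):
            fh.write(f"x,{i},{int(c)}\n")
        for i, c in enumerate(grid.y_marginal):
            fh.write(f"y,{i},{int(c)}\n")

    if config.split_date is not None:
        split = config.split_date
        pts_p1 = [
            gp.point
            for gp in track
            if gp.point is not None and gp.timestamp.date() < split
        ]
        pts_p2 = [
            gp.point
            for gp in track
            if gp.point is not None and gp.timestamp.date() >= split
        ]
        rc1 = quadrant_counts(pts_p1, geom, period=f"before {split.isoformat()}")
        rc2 = quadrant_counts(pts_p2, geom, period=f"from {split.isoformat()}")
        regions_df = pd.DataFrame(
            [
                {"period": rc.period, **rc.as_dict(), "total": rc.total}
                for rc in (rc1, rc2)
            ]
        )
        ratio_df = period_compare(rc1, rc2)
        artifacts["ratios"] = out_dir / "region_ratios.csv"
        with artifacts["ratios"].open("w") as fh:
            fh.write(f"# {REGION_CONVENTION}\n")
            ratio_df.to_csv(fh, index=False)
    else:
        rc = quadrant_counts(points, geom, period="all")
        regions_df = pd.DataFrame(
            [{"period": rc.period, **rc.as_dict(), "total": rc.total}]
        )
    artifacts["regions"] = out_dir / "regions.csv"
    with artifacts["regions"].open("w") as fh:
        fh.write(f"# {REGION_CONVENTION}\n")
        regions_df.to_csv(fh, index=False)

    return PipelineResult(
        config=config, track=track, series=series, artifacts=artifacts
    )


def make_report(out_dir: str | Path, report_dir: Optional[str | Path] = None) -> list[Path]:
    """Render figures from a pipeline output directory.

    Produces the occupancy heatmap with marginal histograms, the daily
    summed-distance bars, and up to four within-day hourly profiles
    (days with maximum, minimum and median daily totals).  Raises
    ReportError when an artifact is missing or the track is empty.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    report_dir = Path(report_dir) if report_dir is not None else out_dir
    report_dir.mkdir(parents=True, exist_ok=True)

    for name in ("track.csv", "daily.csv", "hourly.csv", "occupancy_grid.csv"):
        if not (out_dir / name).exists():
            raise ReportError(f"missing pipeline artifact: {out_dir / name}")

    track = read_track_csv(out_dir / "track.csv")
    present = track.dropna(subset=["x", "y"])
    if present.empty:
        raise ReportError("track has no frames with a group position")
    daily = pd.read_csv(out_dir / "daily.csv")
    hourly = pd.read_csv(out_dir / "hourly.csv")
    grid = np.loadtxt(out_dir / "occupancy_grid.csv", delimiter=",", ndmin=2)

    figures: list[Path] = []

    # density heatmap with marginal histograms
    fig = plt.figure(figsize=(9, 5))
    gs = fig.add_gridspec(
        2, 2, width_ratios=(5, 1), height_ratios=(1, 4), hspace=0.08, wspace=0.08
    )
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    peak = grid.max() if grid.max() > 0 else 1.0
    im = ax.imshow(grid / peak, origin="upper", aspect="auto", cmap="viridis")
    ax.set_xlabel("x bin")
    ax.set_ylabel("y bin")
    ax_top.bar(np.arange(grid.shape[1]), grid.sum(axis=0), width=1.0)
    ax_top.tick_params(labelbottom=False)
    ax_right.barh(np.arange(grid.shape[0]), grid.sum(axis=1), height=1.0)
    ax_right.tick_params(labelleft=False)
    fig.colorbar(im, ax=[ax, ax_right], label="density (0-1, scaled to fullest bin)")
    fig.suptitle(f"Group-position occupancy ({REGION_CONVENTION})", fontsize=9)
    path = report_dir / "occupancy_heatmap.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)

    # daily summed distances
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(daily["day"], daily["total_d"])
    ax.set_ylabel("summed distance (% of diagonal)")
    ax.set_xlabel("day")
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    path = report_dir / "daily_distance.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)

    # within-day hourly profiles: max, min, median day(s)
    order = daily.sort_values("total_d")
    pick: list[str] = []
    for day in (
        order.iloc[-1]["day"],
        order.iloc[0]["day"],
        order.iloc[(len(order) - 1) // 2]["day"],
        order.iloc[len(order) // 2]["day"],
    ):
        if day not in pick:
            pick.append(day)
    n_panels = len(pick)
    fig, axes = plt.subplots(
        (n_panels + 1) // 2, 2, figsize=(9, 2.6 * ((n_panels + 1) // 2)), squeeze=False
    )
    for ax_panel, day in zip(axes.ravel(), pick):
        sub = hourly[hourly["day"] == day]
        ax_panel.bar(sub["hour"], sub["total_d"], width=0.9)
        ax_panel.set_xlim(-0.5, 23.5)
        ax_panel.set_title(
            f"{day} (sum {sub['total_d'].sum():.1f}%)", fontsize=9
        )
        ax_panel.set_xlabel("hour")
        ax_panel.set_ylabel("% of diagonal")
    for ax_panel in axes.ravel()[n_panels:]:
        ax_panel.axis("off")
    fig.tight_layout()
    path = report_dir / "hourly_profiles.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)

    return figures
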