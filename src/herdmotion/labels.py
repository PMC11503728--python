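"""Reading segmentation polygon labels and writing track CSVs.

The on-disk interchange is the YOLO segmentation label dialect: one text
file per frame, one instance per line, `class_id` followed by an even
number (>= 6) of normalized x y vertex pairs in [0, 1], with an optional
trailing confidence token.  A frame manifest (CSV) lists which label file
belongs to which timestamp and what the frame geometry is.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

from .errors import FormatError, ManifestError
from .geometry import Polygon

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["frame_id", "timestamp", "label_path", "width", "height"]
_COORD_SLACK = 1e-6


@dataclass
class FrameRecord:
    """Parsed detections of one frame."""

    frame_id: str
    timestamp: datetime
    image_width: int
    image_height: int
    instances: list[tuple[Polygon, int, Optional[float]]] = field(
        default_factory=list
    )

    @property
    def n_instances(self) -> int:
        return len(self.instances)


@dataclass(frozen=True)
class ManifestEntry:
    frame_id: str
    timestamp: datetime
    label_path: Path
    width: int
    height: int


@dataclass
class FrameManifest:
    """Chronologically ordered list of frames with unique ids."""

    entries: list[ManifestEntry]

    def __post_init__(self):
        ids = [e.frame_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate frame_id(s): {dupes}")
        times = [e.timestamp for e in self.entries]
        for prev, curr in zip(times, times[1:]):
            if curr <= prev:
                raise ManifestError(
                    f"timestamps not strictly increasing at {curr}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def parse_yolo_seg_line(
    line: str,
    image_width: int,
    image_height: int,
    has_confidence: Optional[bool] = None,
) -> tuple[int, Polygon, Optional[float]]:
    """Parse one instance line into (class_id, denormalized Polygon, confidence).

    ``has_confidence=None`` auto-detects the trailing-confidence dialect
    from token-count parity: coordinates always come in pairs, so an odd
    remainder after the class id means the last token is a confidence.
    """
    tokens = line.split()
    if len(tokens) < 7:
        raise FormatError(f"too few tokens ({len(tokens)}) in label line")
    try:
        class_id = int(tokens[0])
        values = [float(t) for t in tokens[1:]]
    except ValueError as exc:
        raise FormatError(f"non-numeric token in label line: {exc}") from None

    if has_confidence is None:
        has_confidence = len(values) % 2 == 1
    confidence: Optional[float] = None
    if has_confidence:
        confidence = values[-1]
        values = values[:-1]
        if not 0.0 <= confidence <= 1.0:
            raise FormatError(f"confidence {confidence} outside [0, 1]")
    if len(values) % 2 == 1:
        raise FormatError("odd coordinate count in label line")
    if len(values) < 6:
        raise FormatError("polygon needs at least 3 vertices")
    for v in values:
        if v < -_COORD_SLACK or v > 1.0 + _COORD_SLACK:
            raise FormatError(f"normalized coordinate {v} outside [0, 1]")

    verts = [
        (
            min(max(values[i], 0.0), 1.0) * image_width,
            min(max(values[i + 1], 0.0), 1.0) * image_height,
        )
        for i in range(0, len(values), 2)
    ]
    return class_id, Polygon(verts), confidence


def _parse_timestamp(raw: str) -> datetime:
    try:
        ts = pd.Timestamp(raw)
    except (ValueError, TypeError) as exc:
        raise ManifestError(f"unparsable timestamp {raw!r}: {exc}") from None
    if pd.isna(ts):
        raise ManifestError(f"unparsable timestamp {raw!r}")
    return ts.to_pydatetime()


def load_manifest(path: str | Path) -> FrameManifest:
    """Load a manifest CSV (frame_id, timestamp, label_path, width, height).

    Relative label paths are resolved against the manifest's directory.
    """
    path = Path(path)
    entries: list[ManifestEntry] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ManifestError(f"manifest missing column(s): {sorted(missing)}")
        for row in reader:
            label_path = Path(row["label_path"])
            if not label_path.is_absolute():
                label_path = path.parent / label_path
            try:
                width = int(row["width"])
                height = int(row["height"])
            except ValueError:
                raise ManifestError(
                    f"bad frame geometry in manifest row {row['frame_id']!r}"
                ) from None
            if width < 1 or height < 1:
                raise ManifestError("frame dimensions must be >= 1")
            entries.append(
                ManifestEntry(
                    frame_id=row["frame_id"],
                    timestamp=_parse_timestamp(row["timestamp"]),
                    label_path=label_path,
                    width=width,
                    height=height,
                )
            )
    return FrameManifest(entries)


def iter_frames(
    manifest: FrameManifest,
    min_confidence: float = 0.0,
    has_confidence: Optional[bool] = None,
) -> Iterator[FrameRecord]:
    """Yield FrameRecords in chronological order.

    A missing label file is treated as a frame with zero detections (a
    gap) and flagged with a warning rather than raised: downstream gap
    policy decides what to do with it.  ``min_confidence`` filters
    instances whose confidence is present and below the threshold.
    """
    for entry in manifest:
        record = FrameRecord(
            frame_id=entry.frame_id,
            timestamp=entry.timestamp,
            image_width=entry.width,
            image_height=entry.height,
        )
        if not entry.label_path.exists():
            warnings.warn(
                f"label file missing for frame {entry.frame_id!r}: "
                f"{entry.label_path} (treated as zero detections)",
                stacklevel=2,
            )
            yield record
            continue
        with entry.label_path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                class_id, poly, conf = parse_yolo_seg_line(
                    line, entry.width, entry.height, has_confidence
                )
                if conf is not None and conf < min_confidence:
                    continue
                record.instances.append((poly, class_id, conf))
        log.debug("frame %s: %d instance(s)", entry.frame_id, record.n_instances)
        yield record


def load_frames(manifest: FrameManifest, **kwargs) -> list[FrameRecord]:
    return list(iter_frames(manifest, **kwargs))


def make_manifest(
    label_paths: Sequence[str | Path],
    start_time: datetime,
    interval_s: float,
    width: int,
    height: int,
    frame_ids: Optional[Sequence[str]] = None,
) -> FrameManifest:
    """Build a manifest from a fixed start time and sampling interval.

    Timestamps always come from a manifest, never from filenames; this
    helper is the sanctioned way to construct one for evenly sampled
    captures.
    """
    if frame_ids is None:
        frame_ids = [Path(p).stem for p in label_paths]
    entries = [
        ManifestEntry(
            frame_id=str(fid),
            timestamp=start_time + timedelta(seconds=i * interval_s),
            label_path=Path(p),
            width=width,
            height=height,
        )
        for i, (fid, p) in enumerate(zip(frame_ids, label_paths))
    ]
    return FrameManifest(entries)


def write_manifest_csv(manifest: FrameManifest, path: str | Path) -> None:
    """Write a manifest CSV; label paths are stored relative to the
    manifest's directory when they live under it, so the scene directory
    stays relocatable."""
    path = Path(path)
    base = path.resolve().parent
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for e in manifest:
            label = Path(e.label_path)
            if label.is_absolute():
                try:
                    label = label.relative_to(base)
                except ValueError:
                    pass
            writer.writerow(
                [
                    e.frame_id,
                    e.timestamp.isoformat(sep=" "),
                    str(label),
                    e.width,
                    e.height,
                ]
            )


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else f"{value:.6f}"


def write_track_csv(rows, path: str | Path) -> None:
    """Write the per-frame group-position track as RFC-4180 CSV.

    ``rows`` is an iterable of (frame_id, timestamp, x, y, n_pigs, D)
    tuples in chronological order; x, y and D may be None (gap frames and
    the first frame / gap-adjacent pairs respectively) and are written as
    empty fields.  Floats are rendered at 6 decimal places.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_id", "timestamp", "x", "y", "n_pigs", "D"])
        for frame_id, timestamp, x, y, n_pigs, d in rows:
            writer.writerow(
                [
                    frame_id,
                    timestamp.isoformat(sep=" "),
                    _fmt(x),
                    _fmt(y),
                    int(n_pigs),
                    _fmt(d),
                ]
            )


def read_track_csv(path: str | Path) -> pd.DataFrame:
    """Read a track CSV back into a DataFrame with parsed timestamps."""
    df = pd.read_csv(path, dtype={"frame_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
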