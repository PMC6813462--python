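"""Domain types and I/O for 3D cell tracks, imaging fields and vessel geometry.

Coordinates are micrometres in a right-handed frame with z increasing with
imaging depth; time is seconds from acquisition start.  A track is one cell's
ordered centroid samples; a field is one imaging volume.  Vessels are encoded
as cylindrical segments (polyline centerline + radius), the geometric
substrate for perivascular classification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRACK_CSV_COLUMNS = [
    "track_id", "cell_type", "field_id", "group", "t_s", "x_um", "y_um", "z_um",
]


class TrackDataError(ValueError):
    """Malformed or inconsistent track/vessel input."""


@dataclass(frozen=True)
class TimePoint:
    """One centroid sample: elapsed time t (s) and position x, y, z (μm)."""

    t: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise TrackDataError(f"negative time {self.t}")
        for v in (self.t, self.x, self.y, self.z):
            if not math.isfinite(v):
                raise TrackDataError("non-finite coordinate or time")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Track:
    """An ordered sequence of centroid samples for one cell.

    ``cell_type`` and ``group`` are free labels (e.g. Th1/Th17, CTRL/antiLFA1)
    preserved verbatim from the input file.
    """

    track_id: str
    cell_type: str
    field_id: str
    group: str
    points: list[TimePoint]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise TrackDataError(
                f"track {self.track_id!r} has {len(self.points)} point(s); need >=2"
            )
        times = [p.t for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise TrackDataError(
                f"track {self.track_id!r}: time points not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, shape (n,)."""
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        """Centroid positions in μm, shape (n, 3)."""
        return np.array([[p.x, p.y, p.z] for p in self.points], dtype=float)

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return self.points[-1].t - self.points[0].t


@dataclass(frozen=True)
class FieldMeta:
    """Metadata for one imaging field (volume of acquisition)."""

    field_id: str
    mouse_id: str = ""
    n_cells_visible: int = 0
    volume_dims: tuple[float, float, float] = (100.0, 120.0, 70.0)

    def __post_init__(self) -> None:
        if self.n_cells_visible < 0:
            raise TrackDataError("n_cells_visible must be >= 0")
        if any(d <= 0 for d in self.volume_dims):
            raise TrackDataError("field extents must be positive")


@dataclass(frozen=True)
class VesselSegment:
    """A cylindrical vessel piece: polyline centerline (μm) and radius (μm)."""

    centerline: np.ndarray  # (k, 3) float, k >= 2
    radius_um: float

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
            raise TrackDataError("centerline must be an (k>=2, 3) point array")
        if not np.all(np.isfinite(cl)):
            raise TrackDataError("non-finite centerline point")
        if not (self.radius_um > 0):
            raise TrackDataError(f"vessel radius must be > 0, got {self.radius_um}")
        object.__setattr__(self, "centerline", cl)


@dataclass(frozen=True)
class VesselGeometry:
    """A set of vessel segments.  Empty geometry is valid (no vessels imaged)."""

    segments: tuple[VesselSegment, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def is_empty(self) -> bool:
        return len(self.segments) == 0


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry of the two-photon time-lapse volumes.

    Defaults reflect typical intravital spinal-cord acquisitions: a
    100 × 120 μm field sampled at 2 pixels/μm, 28 z-steps of 2.5 μm
    (70 μm depth), frames every 35–40 s, for up to 30 min.
    """

    frame_interval: float = 37.5   # s
    xy_pixel_size: float = 0.5     # μm
    z_step: float = 2.5            # μm
    field_xy: tuple[float, float] = (100.0, 120.0)  # μm
    n_z_steps: int = 28
    max_duration: float = 1800.0   # s

    def __post_init__(self) -> None:
        vals = (self.frame_interval, self.xy_pixel_size, self.z_step,
                *self.field_xy, self.n_z_steps, self.max_duration)
        if any(v <= 0 for v in vals):
            raise TrackDataError("all ImagingConfig values must be positive")

    @property
    def depth(self) -> float:
        """Total imaged depth in μm (n_z_steps × z_step)."""
        return self.n_z_steps * self.z_step

    @property
    def volume_dims(self) -> tuple[float, float, float]:
        return (self.field_xy[0], self.field_xy[1], self.depth)


@dataclass(frozen=True)
class FilterPolicy:
    """Track- and field-level inclusion thresholds.

    Both the point-count and the duration rule are enforced conjunctively:
    the two stated inclusion phrasings ("greater than 3 min", ">=12 time
    points") disagree at 35–40 s frame intervals, so the conservative
    intersection is used, each rule independently configurable.
    """

    min_points: int = 12
    min_duration: float = 180.0    # s
    min_field_cells: int = 20

    def __post_init__(self) -> None:
        if self.min_points < 2:
            raise TrackDataError("min_points must be >= 2")


@dataclass
class FilterReport:
    """Per-rule rejection counts from :func:`apply_filters`."""

    n_input: int = 0
    n_kept: int = 0
    rejected_points: int = 0
    rejected_duration: int = 0
    rejected_field: int = 0
    rejected_ids: dict[str, str] = dc_field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_kept

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_rejected": self.n_rejected,
            "rejected_points": self.rejected_points,
            "rejected_duration": self.rejected_duration,
            "rejected_field": self.rejected_field,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flatten tracks into the canonical long-format table (one row per sample)."""
    rows = []
    for tr in tracks:
        for p in tr.points:
            rows.append((tr.track_id, tr.cell_type, tr.field_id, tr.group,
                         p.t, p.x, p.y, p.z))
    return pd.DataFrame(rows, columns=TRACK_CSV_COLUMNS)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Group a long-format table into Track objects, sorting each by time."""
    missing = [c for c in TRACK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrackDataError(f"missing track-CSV columns: {missing}")
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        if grp["t_s"].duplicated().any():
            t_dup = grp.loc[grp["t_s"].duplicated(), "t_s"].iloc[0]
            raise TrackDataError(
                f"duplicate sample for track {tid!r} at t={t_dup}"
            )
        labels = {c: grp[c].iloc[0] for c in ("cell_type", "field_id", "group")}
        for c, v in labels.items():
            if (grp[c] != v).any():
                raise TrackDataError(f"track {tid!r} has inconsistent {c} labels")
        pts = [TimePoint(t=float(r.t_s), x=float(r.x_um), y=float(r.y_um),
                         z=float(r.z_um)) for r in grp.itertuples()]
        tracks.append(Track(track_id=str(tid), points=pts, **labels))
    return tracks


def read_tracks(path: str | Path) -> list[Track]:
    """Read a track-CSV file (header: track_id,...,z_um) into Track objects.

    Rows may appear in any order; each track is sorted by time.  Malformed
    numeric fields and duplicate (track_id, t) samples raise
    :class:`TrackDataError` naming the offending location.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={
            "track_id": str, "cell_type": str, "field_id": str, "group": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise TrackDataError(f"cannot parse {path}: {exc}") from exc
    for col in ("t_s", "x_um", "y_um", "z_um"):
        if col in df.columns:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                # +2: header line plus 1-based indexing
                raise TrackDataError(
                    f"{path}: malformed numeric value in column {col!r} "
                    f"at line {bad.index[0] + 2}"
                )
            df[col] = pd.to_numeric(df[col])
    return frame_to_tracks(df)


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks as track-CSV; positions/times rounded to 3 decimals
    (sub-nanometre precision is meaningless at 0.5 μm pixels)."""
    df = tracks_to_frame(tracks)
    df.to_csv(path, index=False, float_format="%.3f")


def read_vessels(path: str | Path) -> VesselGeometry:
    """Read vessel geometry from JSON: {"segments": [{"centerline": [[x,y,z],...],
    "radius_um": r}, ...]}.  Validates radii and centerline lengths."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return vessels_from_dict(data)


def vessels_from_dict(data: Mapping) -> VesselGeometry:
    if "segments" not in data:
        raise TrackDataError("vessel JSON must contain a 'segments' list")
    segs = [VesselSegment(centerline=np.asarray(s["centerline"], dtype=float),
                          radius_um=float(s["radius_um"]))
            for s in data["segments"]]
    return VesselGeometry(segments=tuple(segs))


def write_vessels(geometry: VesselGeometry, path: str | Path) -> None:
    data = {"segments": [
        {"centerline": seg.centerline.tolist(), "radius_um": seg.radius_um}
        for seg in geometry.segments]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_filters(
    tracks: Sequence[Track],
    fields: Mapping[str, FieldMeta] | Iterable[FieldMeta],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[list[Track], FilterReport]:
    """Apply track- and field-level inclusion rules.

    A track is kept iff it has >= ``policy.min_points`` samples AND spans
    >= ``policy.min_duration`` seconds AND its field contains
    >= ``policy.min_field_cells`` visible cells.  Returns the kept tracks and
    a report counting rejections per rule (a track failing several rules is
    charged to the first failing rule, in the order points, duration, field).

    Raises :class:`TrackDataError` for a track whose field_id is unknown.
    """
    if not isinstance(fields, Mapping):
        fields = {f.field_id: f for f in fields}
    report = FilterReport(n_input=len(tracks))
    kept: list[Track] = []
    for tr in tracks:
        if tr.field_id not in fields:
            raise TrackDataError(
                f"track {tr.track_id!r} references unknown field {tr.field_id!r}"
            )
        if len(tr) < policy.min_points:
            report.rejected_points += 1
            report.rejected_ids[tr.track_id] = "points"
        elif tr.duration < policy.min_duration:
            report.rejected_duration += 1
            report.rejected_ids[tr.track_id] = "duration"
        elif fields[tr.field_id].n_cells_visible < policy.min_field_cells:
            report.rejected_field += 1
            report.rejected_ids[tr.track_id] = "field"
        else:
            kept.append(tr)
    report.n_kept = len(kept)
    return kept, report
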