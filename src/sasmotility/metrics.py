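"""Per-track and cohort motility statistics.

Definitions follow the standard intravital-imaging conventions:

* instantaneous velocity — centroid displacement between adjacent frames
  divided by the frame interval, in μm/min;
* track (mean) velocity — unweighted mean of a track's instantaneous
  velocities over all intervals;
* arrest index — duration-weighted fraction of a track's intervals at
  speed ≤ 2 μm/min (for constant frame intervals this equals the fraction
  of time points at which the cell is not moving);
* meandering index — net displacement from origin divided by total path
  length (1 = perfectly straight, 0 = returns to origin);
* displacement curve — cohort mean of |p(τ) − p(0)| vs elapsed time τ,
  which grows linearly in √τ for a random walk and linearly in τ for
  ballistic motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .track_model import Track

SEC_PER_MIN = 60.0

#: Speed below which a cell is considered not to be moving (μm/min).
DEFAULT_ARREST_THRESHOLD = 2.0


@dataclass
class MotilityRecord:
    """Derived motility metrics for one track."""

    track_id: str
    cell_type: str
    field_id: str
    group: str
    n_points: int
    duration: float                      # s
    mean_velocity: float                 # μm/min
    path_length: float                   # μm
    net_displacement: float              # μm
    meandering_index: float              # ∈ [0, 1]
    arrest_index: float                  # ∈ [0, 1]
    n_arrest_episodes: int


@dataclass
class DisplacementCurve:
    """Cohort mean displacement (or MSD) vs elapsed time on a regular grid.

    Tracks shorter than a grid time drop out of that point's average, so
    ``n_tracks`` is non-increasing along the grid.
    """

    time_grid: np.ndarray        # s, starts at 0
    mean: np.ndarray             # μm (or μm² for MSD)
    sem: np.ndarray
    n_tracks: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tau_s": self.time_grid, "mean": self.mean,
            "sem": self.sem, "n": self.n_tracks,
        })


# ---------------------------------------------------------------------------
# per-track metrics
# ---------------------------------------------------------------------------

def _steps(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Return per-interval (step length μm, Δt s)."""
    pos = track.positions
    dt = np.diff(track.times)
    if np.any(dt <= 0):
        raise ValueError(f"track {track.track_id!r}: non-positive time step")
    d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return d, dt


def instantaneous_speeds(track: Track) -> np.ndarray:
    """Speed of each interval in μm/min; length n_points − 1."""
    d, dt = _steps(track)
    return d / dt * SEC_PER_MIN


def mean_track_velocity(track: Track) -> float:
    """Unweighted mean of the instantaneous speeds (μm/min)."""
    return float(np.mean(instantaneous_speeds(track)))


def path_length(track: Track) -> float:
    """Total path length in μm."""
    d, _ = _steps(track)
    return float(d.sum())


def net_displacement(track: Track) -> float:
    """Straight-line distance from first to last point (μm)."""
    pos = track.positions
    return float(np.linalg.norm(pos[-1] - pos[0]))


def meandering_index(track: Track) -> float:
    """Net displacement / path length; 0 by convention for a zero-length path."""
    pl = path_length(track)
    if pl == 0.0:
        return 0.0
    return net_displacement(track) / pl


def arrest_index(
    track: Track, threshold: float = DEFAULT_ARREST_THRESHOLD
) -> float:
    """Duration-weighted fraction of intervals at speed ≤ ``threshold`` μm/min."""
    if threshold < 0:
        raise ValueError(f"arrest threshold must be >= 0, got {threshold}")
    speeds = instantaneous_speeds(track)
    _, dt = _steps(track)
    return float(dt[speeds <= threshold].sum() / dt.sum())


def arrest_episodes(
    track: Track, threshold: float = DEFAULT_ARREST_THRESHOLD
) -> int:
    """Number of maximal runs of consecutive sub-threshold intervals
    (a count of discrete stops in stop-and-go motility)."""
    below = instantaneous_speeds(track) <= threshold
    # an episode starts where `below` turns True
    starts = below & ~np.concatenate(([False], below[:-1]))
    return int(starts.sum())


def motility_record(
    track: Track, threshold: float = DEFAULT_ARREST_THRESHOLD
) -> MotilityRecord:
    """All per-track metrics in one record."""
    return MotilityRecord(
        track_id=track.track_id,
        cell_type=track.cell_type,
        field_id=track.field_id,
        group=track.group,
        n_points=len(track),
        duration=track.duration,
        mean_velocity=mean_track_velocity(track),
        path_length=path_length(track),
        net_displacement=net_displacement(track),
        meandering_index=meandering_index(track),
        arrest_index=arrest_index(track, threshold),
        n_arrest_episodes=arrest_episodes(track, threshold),
    )


def metrics_table(
    tracks: Iterable[Track], threshold: float = DEFAULT_ARREST_THRESHOLD
) -> pd.DataFrame:
    """One MotilityRecord row per track."""
    recs = [motility_record(t, threshold) for t in tracks]
    return pd.DataFrame([r.__dict__ for r in recs])


# ---------------------------------------------------------------------------
# cohort curves
# ---------------------------------------------------------------------------

def _displacement_at(track: Track, taus: np.ndarray) -> np.ndarray:
    """|p(τ) − p(0)| with linear interpolation between frames; NaN past the
    track's end."""
    t = track.times - track.times[0]
    pos = track.positions
    out = np.full(len(taus), np.nan)
    valid = taus <= t[-1] + 1e-9
    tv = np.clip(taus[valid], 0.0, t[-1])
    interp = np.column_stack([np.interp(tv, t, pos[:, k]) for k in range(3)])
    out[valid] = np.linalg.norm(interp - pos[0], axis=1)
    return out


def _curve(tracks: Sequence[Track], grid_step: float,
           square: bool) -> DisplacementCurve:
    if not tracks:
        raise ValueError("displacement curve requires at least one track")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    max_dur = max(tr.duration for tr in tracks)
    grid = np.arange(0.0, max_dur + grid_step / 2, grid_step)
    disp = np.vstack([_displacement_at(tr, grid) for tr in tracks])
    if square:
        disp = disp ** 2
    n = np.sum(~np.isnan(disp), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(disp, axis=0)
        sd = np.nanstd(disp, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return DisplacementCurve(time_grid=grid, mean=mean, sem=sem, n_tracks=n)


def displacement_curve(
    tracks: Sequence[Track], grid_step: float
) -> DisplacementCurve:
    """Cohort mean displacement from origin vs elapsed time.

    For each grid time τ, the mean (with SEM) over all tracks of duration
    ≥ τ of the interpolated distance from the track's first point.
    """
    return _curve(tracks, grid_step, square=False)


def msd_curve(tracks: Sequence[Track], grid_step: float) -> DisplacementCurve:
    """Mean squared displacement (μm²) vs elapsed time — the companion
    diagnostic: linear in τ for a random walk, quadratic for ballistic motion."""
    return _curve(tracks, grid_step, square=True)


def normalize_trajectories(tracks: Iterable[Track]) -> list[np.ndarray]:
    """Translate each track so its first point is the origin (no rotation);
    the star-plot representation of a cohort's trajectories."""
    return [tr.positions - tr.positions[0] for tr in tracks]
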