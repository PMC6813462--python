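"""Behavioral classification of tracks relative to the vessel network.

Extravasated cells fall into three subsets:

* ``stationary`` — mean track velocity at or below a threshold (2 μm/min);
* ``perivascular_motile`` — motile cells that stay close to the abluminal
  vessel surface for most of their track;
* ``nonperivascular_motile`` — motile cells dispersed in the tissue.

"Close to the vessel" is not a universally agreed constant, so the distance
(default 10 μm, about one cell diameter from the vessel surface) and the
required duration-weighted fraction of time spent near (default 0.8) are
explicit parameters echoed into every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import DEFAULT_ARREST_THRESHOLD, mean_track_velocity
from .track_model import FieldMeta, Track, VesselGeometry

STATIONARY = "stationary"
PERIVASCULAR = "perivascular_motile"
NONPERIVASCULAR = "nonperivascular_motile"
CLASS_LABELS = (STATIONARY, PERIVASCULAR, NONPERIVASCULAR)

DEFAULT_NEAR_DISTANCE = 10.0   # μm from vessel surface
DEFAULT_NEAR_FRACTION = 0.8    # duration-weighted fraction of time


@dataclass
class TrackClass:
    """Classification result for one track."""

    label: str
    mean_velocity: float                # μm/min
    mean_vessel_distance: float         # μm; inf if no vessel geometry
    frac_time_near_vessel: float        # ∈ [0,1]; NaN if no vessel geometry
    vessel_metrics_available: bool = True


@dataclass
class PopulationSummary:
    """Per-field class fractions with cohort mean ± SEM across fields."""

    per_field: pd.DataFrame      # index field_id, columns CLASS_LABELS
    cohort_mean: pd.Series
    cohort_sem: pd.Series
    n_fields: int


# ---------------------------------------------------------------------------
# vessel geometry
# ---------------------------------------------------------------------------

def _segment_axis_distances(points: np.ndarray, centerline: np.ndarray
                            ) -> np.ndarray:
    """Distance from each point (n,3) to a polyline (k,3): min over the
    polyline's straight pieces of the point-to-segment distance."""
    a = centerline[:-1]                       # (k-1, 3)
    ab = centerline[1:] - a                   # (k-1, 3)
    ab2 = np.einsum("ij,ij->i", ab, ab)       # (k-1,)
    ap = points[:, None, :] - a[None, :, :]   # (n, k-1, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nij,ij->ni", ap, ab) / ab2
    t = np.nan_to_num(t, nan=0.0)             # zero-length pieces
    t = np.clip(t, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def vessel_distances(points: np.ndarray, vessels: VesselGeometry) -> np.ndarray:
    """Distance (μm) from each point to the nearest vessel *surface*,
    floored at 0 (points inside a lumen score 0).  Empty geometry → +inf."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if vessels.is_empty:
        return np.full(len(points), np.inf)
    per_seg = np.stack([
        _segment_axis_distances(points, seg.centerline) - seg.radius_um
        for seg in vessels.segments
    ])
    return np.maximum(per_seg.min(axis=0), 0.0)


def vessel_distance(point: Sequence[float], vessels: VesselGeometry) -> float:
    """Scalar convenience wrapper around :func:`vessel_distances`."""
    return float(vessel_distances(np.asarray(point, dtype=float)[None, :],
                                  vessels)[0])


def nearest_surface_pullback(points: np.ndarray, vessels: VesselGeometry,
                             shell: float) -> np.ndarray:
    """Project points that are further than ``shell`` μm from the nearest
    vessel surface radially back onto the shell.  Used by the
    vessel-following generator mode."""
    points = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    if vessels.is_empty:
        raise ValueError("cannot pull back onto an empty vessel geometry")
    # nearest axis point (and that segment's radius) per input point
    best_d = np.full(len(points), np.inf)
    best_axis = np.zeros_like(points)
    radii = np.zeros(len(points))
    idx = np.arange(len(points))
    for seg in vessels.segments:
        a = seg.centerline[:-1]
        ab = seg.centerline[1:] - a
        ab2 = np.einsum("ij,ij->i", ab, ab)
        ap = points[:, None, :] - a[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.einsum("nij,ij->ni", ap, ab) / ab2
        t = np.clip(np.nan_to_num(t, nan=0.0), 0.0, 1.0)
        closest = a[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(points[:, None, :] - closest, axis=2)
        j = d.argmin(axis=1)
        surf = d[idx, j] - seg.radius_um
        better = surf < best_d
        best_d = np.where(better, surf, best_d)
        best_axis[better] = closest[idx, j][better]
        radii[better] = seg.radius_um
    too_far = best_d > shell
    if np.any(too_far):
        vec = points[too_far] - best_axis[too_far]
        norm = np.linalg.norm(vec, axis=1, keepdims=True)
        # degenerate on-axis points keep their position (already inside)
        ok = norm[:, 0] > 1e-12
        unit = np.where(ok[:, None], vec / np.where(ok[:, None], norm, 1.0), 0.0)
        target = best_axis[too_far] + unit * (radii[too_far] + shell)[:, None]
        points[too_far] = np.where(ok[:, None], target, points[too_far])
    return points


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _point_weights(times: np.ndarray) -> np.ndarray:
    """Trapezoidal per-point time weights: half of each adjacent interval."""
    dt = np.diff(times)
    w = np.zeros(len(times))
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return w


def classify_track(
    track: Track,
    vessels: VesselGeometry,
    stationary_threshold: float = DEFAULT_ARREST_THRESHOLD,
    near_distance: float = DEFAULT_NEAR_DISTANCE,
    near_fraction: float = DEFAULT_NEAR_FRACTION,
) -> TrackClass:
    """Assign a track to one of the three behavioral subsets.

    Stationary takes precedence (mean velocity ≤ ``stationary_threshold``,
    regardless of position).  A motile track is perivascular when its
    distance to the nearest vessel surface is ≤ ``near_distance`` for at
    least ``near_fraction`` of its duration-weighted time; otherwise it is
    non-perivascular.  With empty vessel geometry, motile tracks are
    classified non-perivascular and the vessel metrics flagged unavailable.
    """
    v = mean_track_velocity(track)
    dists = vessel_distances(track.positions, vessels)
    available = not vessels.is_empty
    if available:
        w = _point_weights(track.times)
        frac_near = float(w[dists <= near_distance].sum() / w.sum())
        mean_dist = float(np.average(dists, weights=w))
    else:
        frac_near = float("nan")
        mean_dist = float("inf")
    if v <= stationary_threshold:
        label = STATIONARY
    elif available and frac_near >= near_fraction:
        label = PERIVASCULAR
    else:
        label = NONPERIVASCULAR
    return TrackClass(label=label, mean_velocity=v,
                      mean_vessel_distance=mean_dist,
                      frac_time_near_vessel=frac_near,
                      vessel_metrics_available=available)


def classification_table(
    tracks: Iterable[Track],
    vessels: VesselGeometry,
    stationary_threshold: float = DEFAULT_ARREST_THRESHOLD,
    near_distance: float = DEFAULT_NEAR_DISTANCE,
    near_fraction: float = DEFAULT_NEAR_FRACTION,
) -> pd.DataFrame:
    """One classification row per track, with the thresholds echoed so every
    output records the convention that produced it."""
    rows = []
    for tr in tracks:
        c = classify_track(tr, vessels, stationary_threshold,
                           near_distance, near_fraction)
        rows.append({
            "track_id": tr.track_id, "cell_type": tr.cell_type,
            "field_id": tr.field_id, "group": tr.group, "label": c.label,
            "mean_velocity": c.mean_velocity,
            "mean_vessel_distance": c.mean_vessel_distance,
            "frac_time_near_vessel": c.frac_time_near_vessel,
            "stationary_threshold_um_min": stationary_threshold,
            "near_distance_um": near_distance,
            "near_fraction": near_fraction,
        })
    return pd.DataFrame(rows)


def population_fractions(
    classes: pd.DataFrame,
    fields: Mapping[str, FieldMeta] | Iterable[FieldMeta] | None = None,
) -> PopulationSummary:
    """Per-field class fractions and their cohort mean ± SEM *across fields*
    (matching how imaging studies summarize n fields, not n cells).

    ``classes`` is the output of :func:`classification_table`.  Fields listed
    in ``fields`` but containing no classified track are excluded with a
    warning.
    """
    if "field_id" not in classes or "label" not in classes:
        raise ValueError("classes table must have field_id and label columns")
    counts = (classes.groupby(["field_id", "label"]).size()
              .unstack(fill_value=0)
              .reindex(columns=CLASS_LABELS, fill_value=0))
    if fields is not None:
        if not isinstance(fields, Mapping):
            fields = {f.field_id: f for f in fields}
        empty = sorted(set(fields) - set(counts.index))
        if empty:
            warnings.warn(
                f"fields with no classified tracks excluded: {empty}",
                stacklevel=2)
    frac = counts.div(counts.sum(axis=1), axis=0)
    sem = frac.std(axis=0, ddof=1) / np.sqrt(len(frac)) if len(frac) > 1 \
        else frac.iloc[0] * 0.0
    return PopulationSummary(per_field=frac, cohort_mean=frac.mean(axis=0),
                             cohort_sem=sem, n_fields=len(frac))
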