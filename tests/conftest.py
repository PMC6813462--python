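import numpy as np
import pytest

from sasmotility import (FieldMeta, SyntheticParams, TimePoint, Track,
                         VesselGeometry, VesselSegment, generate_cohort)


def make_track(times, positions, track_id="T1", cell_type="Th1",
               field_id="F1", group="CTRL") -> Track:
    pts = [TimePoint(t=float(t), x=float(p[0]), y=float(p[1]), z=float(p[2]))
           for t, p in zip(times, positions)]
    return Track(track_id=track_id, cell_type=cell_type, field_id=field_id,
                 group=group, points=pts)


def random_tracks(n_tracks, rng, n_points_range=(5, 30)) -> list[Track]:
    """Irregularly sampled random tracks covering a wide metric range."""
    out = []
    for i in range(n_tracks):
        n = int(rng.integers(*n_points_range))
        dt = rng.uniform(20.0, 60.0, n - 1)
        times = np.concatenate([[0.0], np.cumsum(dt)])
        positions = np.cumsum(rng.normal(0.0, 3.0, (n, 3)), axis=0)
        out.append(make_track(times, positions, track_id=f"R{i:04d}"))
    return out


@pytest.fixture
def straight_vessel() -> VesselGeometry:
    """One straight segment along x at y=60, z=35, radius 10 μm."""
    return VesselGeometry((VesselSegment(
        centerline=np.array([[0.0, 60.0, 35.0], [100.0, 60.0, 35.0]]),
        radius_um=10.0),))


@pytest.fixture
def small_cohort() -> list[Track]:
    params = SyntheticParams(mode="two_state", n_tracks=20, n_points=15,
                             seed=42)
    return generate_cohort(params)


@pytest.fixture
def default_fields() -> dict[str, FieldMeta]:
    return {"F1": FieldMeta(field_id="F1", n_cells_visible=30)}
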