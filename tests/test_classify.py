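"""Vessel-distance geometry and three-subset behavioral classification."""

import numpy as np
import pytest

import oracles
from conftest import make_track
from sasmotility import (FieldMeta, SyntheticParams, VesselGeometry,
                         classification_table, classify_track,
                         generate_cohort, population_fractions,
                         vessel_distance, vessel_distances)
from sasmotility.classify import (NONPERIVASCULAR, PERIVASCULAR, STATIONARY)
from sasmotility.track_model import VesselSegment


class TestVesselDistance:
    def test_cylinder_geometry(self, straight_vessel):
        assert vessel_distance([50, 75, 35], straight_vessel) == \
            pytest.approx(5.0)

    def test_point_on_axis_is_zero(self, straight_vessel):
        assert vessel_distance([50, 60, 35], straight_vessel) == 0.0

    def test_inside_lumen_floored_at_zero(self, straight_vessel):
        assert vessel_distance([50, 65, 35], straight_vessel) == 0.0

    def test_empty_geometry_is_infinite(self):
        assert vessel_distance([0, 0, 0], VesselGeometry()) == np.inf

    def test_beyond_endpoint_uses_endpoint(self, straight_vessel):
        # 20 μm past the x=100 end, on-axis: distance 20 − 10 = 10
        assert vessel_distance([120, 60, 35], straight_vessel) == \
            pytest.approx(10.0)

    def test_matches_dense_polyline_sampling(self):
        rng = np.random.default_rng(2)
        cl = np.cumsum(rng.uniform(-20, 20, (5, 3)), axis=0) + 50
        geo = VesselGeometry((VesselSegment(cl, 7.0),))
        for _ in range(20):
            pt = rng.uniform(0, 100, 3)
            got = vessel_distance(pt, geo)
            want = oracles.vessel_distance_dense(pt, cl.tolist(), 7.0)
            assert got == pytest.approx(want, abs=0.1)


class TestClassifyTrack:
    def test_slow_track_stationary_regardless_of_position(self,
                                                          straight_vessel):
        # mean velocity 1.5 μm/min, sitting right on the vessel wall
        pos = np.outer(np.arange(12) * 1.5 / 60 * 37.5, [1., 0, 0]) \
            + [40, 70, 35]
        tr = make_track(np.arange(12) * 37.5, pos)
        assert classify_track(tr, straight_vessel).label == STATIONARY

    def test_vessel_following_track_is_perivascular(self, straight_vessel):
        p = SyntheticParams(mode="vessel_following", v_motile_mean=6.0,
                            p_stop=0.0, p_go=1.0, shell_um=5.0,
                            n_tracks=10, n_points=15, seed=12)
        for tr in generate_cohort(p, vessels=straight_vessel):
            assert classify_track(tr, straight_vessel).label == PERIVASCULAR

    def test_far_brownian_track_is_nonperivascular(self, straight_vessel):
        p = SyntheticParams(mode="brownian", v_motile_mean=6.0,
                            v_motile_sd=1.0, p_stop=0.0, p_go=1.0,
                            n_tracks=5, n_points=15, seed=13)
        for tr in generate_cohort(p):
            far = make_track(tr.times, tr.positions + [0.0, 500.0, 0.0])
            c = classify_track(far, straight_vessel)
            assert c.label == NONPERIVASCULAR
            assert c.mean_vessel_distance > 300

    def test_missing_vessels_flags_metrics_unavailable(self):
        tr = make_track(np.arange(12) * 37.5,
                        np.outer(np.arange(12), [3.0, 0, 0]))
        c = classify_track(tr, VesselGeometry())
        assert c.label == NONPERIVASCULAR
        assert not c.vessel_metrics_available
        assert np.isnan(c.frac_time_near_vessel)

    def test_monotone_in_stationary_threshold(self, straight_vessel,
                                              small_cohort):
        for thr_lo, thr_hi in [(1.0, 2.0), (2.0, 4.0)]:
            for tr in small_cohort:
                lo = classify_track(tr, straight_vessel, thr_lo).label
                hi = classify_track(tr, straight_vessel, thr_hi).label
                if lo == STATIONARY:
                    assert hi == STATIONARY

    def test_near_distance_limits(self, straight_vessel, small_cohort):
        for tr in small_cohort:
            wide = classify_track(tr, straight_vessel, near_distance=1e9)
            tight = classify_track(tr, straight_vessel, near_distance=0.0)
            if wide.label != STATIONARY:
                assert wide.label == PERIVASCULAR
            assert tight.label != PERIVASCULAR or \
                tight.frac_time_near_vessel >= 0.8


class TestPopulationFractions:
    def _classes(self, labels_by_field):
        import pandas as pd
        rows = [{"field_id": f, "label": lab}
                for f, labs in labels_by_field.items() for lab in labs]
        return pd.DataFrame(rows)

    def test_single_field_fractions(self):
        cls = self._classes({"F1": [STATIONARY] * 2 + [NONPERIVASCULAR] * 8})
        s = population_fractions(cls)
        assert s.cohort_mean[STATIONARY] == pytest.approx(0.2)
        assert s.per_field.loc["F1"].sum() == pytest.approx(1.0)

    def test_identical_fields_have_zero_sem(self):
        labs = [STATIONARY] * 2 + [PERIVASCULAR] * 3 + [NONPERIVASCULAR] * 5
        s = population_fractions(self._classes({"F1": labs, "F2": labs}))
        assert np.allclose(s.cohort_sem.values, 0.0)

    def test_fractions_sum_to_one_per_field(self, straight_vessel):
        p = SyntheticParams(mode="two_state", n_tracks=40, n_points=15,
                            seed=14)
        cls = classification_table(generate_cohort(p), straight_vessel)
        s = population_fractions(cls)
        np.testing.assert_allclose(s.per_field.sum(axis=1), 1.0)

    def test_empty_field_excluded_with_warning(self):
        cls = self._classes({"F1": [STATIONARY] * 5})
        fields = {"F1": FieldMeta("F1", n_cells_visible=25),
                  "F2": FieldMeta("F2", n_cells_visible=25)}
        with pytest.warns(UserWarning, match="F2"):
            s = population_fractions(cls, fields)
        assert s.n_fields == 1

    def test_known_mixture_recovered_over_fields(self, straight_vessel):
        # 6 fields × (6 stationary / 6 perivascular / 18 free) = 0.2/0.2/0.6
        tracks = []
        for k in range(6):
            common = dict(n_points=15, frame_interval=37.5)
            stat = SyntheticParams(mode="two_state", p_stop=1.0, p_go=0.0,
                                   v_arrest_mean=0.0, n_tracks=6,
                                   seed=100 + k, **common)
            peri = SyntheticParams(mode="vessel_following", v_motile_mean=8.0,
                                   p_stop=0.0, p_go=1.0, shell_um=4.0,
                                   n_tracks=6, seed=200 + k, **common)
            free = SyntheticParams(mode="brownian", v_motile_mean=8.0,
                                   v_motile_sd=1.0, p_stop=0.0, p_go=1.0,
                                   n_tracks=18, seed=300 + k, **common)
            fid = f"F{k + 1}"
            for i, tr in enumerate(generate_cohort(stat, field_id=fid)):
                tr.track_id = f"{fid}s{i}"; tracks.append(tr)
            for i, tr in enumerate(generate_cohort(
                    peri, vessels=straight_vessel, field_id=fid)):
                tr.track_id = f"{fid}p{i}"; tracks.append(tr)
            for i, tr in enumerate(generate_cohort(free, field_id=fid)):
                far = make_track(tr.times, tr.positions + [0, 400.0, 0],
                                 track_id=f"{fid}f{i}", field_id=fid)
                tracks.append(far)
        cls = classification_table(tracks, straight_vessel)
        s = population_fractions(cls)
        se = np.sqrt(0.2 * 0.8 / 180)
        assert abs(s.cohort_mean[STATIONARY] - 0.2) <= 3 * se
        assert abs(s.cohort_mean[PERIVASCULAR] - 0.2) <= 3 * se
        assert abs(s.cohort_mean[NONPERIVASCULAR] - 0.6) <= \
            3 * np.sqrt(0.6 * 0.4 / 180)
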