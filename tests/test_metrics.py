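"""Per-track motility metrics and cohort displacement/MSD curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_track, random_tracks
from sasmotility import (SyntheticParams, arrest_episodes, arrest_index,
                         displacement_curve, generate_cohort,
                         instantaneous_speeds, mean_track_velocity,
                         meandering_index, metrics_table, msd_curve,
                         normalize_trajectories)


class TestInstantaneousSpeeds:
    def test_single_interval(self):
        tr = make_track([0, 60], [[0, 0, 0], [3, 0, 0]])
        np.testing.assert_allclose(instantaneous_speeds(tr), [3.0])

    def test_stationary_track(self):
        tr = make_track(np.arange(5) * 37.5, np.zeros((5, 3)))
        np.testing.assert_allclose(instantaneous_speeds(tr), np.zeros(4))

    def test_euclidean_345_triangle(self):
        tr = make_track([0, 60, 120],
                        [[0, 0, 0], [3, 0, 0], [3, 4, 0]])
        np.testing.assert_allclose(instantaneous_speeds(tr), [3.0, 4.0])

    def test_mean_of_speeds(self):
        tr = make_track([0, 60, 120],
                        [[0, 0, 0], [3, 0, 0], [3, 6, 0]])
        assert mean_track_velocity(tr) == pytest.approx(4.5)


class TestMeanderingIndex:
    def test_straight_track_is_one(self):
        tr = make_track(np.arange(5) * 37.5,
                        np.outer(np.arange(5), [1.0, 2.0, 0.5]))
        assert meandering_index(tr) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        sq = [[0, 0, 0], [5, 0, 0], [5, 5, 0], [0, 5, 0], [0, 0, 0]]
        tr = make_track(np.arange(5) * 37.5, sq)
        assert meandering_index(tr) == pytest.approx(0.0)

    def test_pythagorean_path(self):
        tr = make_track([0, 60, 120],
                        [[0, 0, 0], [3, 0, 0], [3, 4, 0]])
        assert meandering_index(tr) == pytest.approx(5.0 / 7.0)

    def test_zero_path_convention(self):
        tr = make_track([0, 60], [[1, 1, 1], [1, 1, 1]])
        assert meandering_index(tr) == 0.0


class TestArrestIndex:
    def test_fraction_of_slow_intervals(self):
        # 10 equal 60 s intervals: 4 at 1 μm/min, 6 at 5 μm/min
        steps = [1.0] * 4 + [5.0] * 6
        pos = np.zeros((11, 3))
        pos[1:, 0] = np.cumsum(steps)
        tr = make_track(np.arange(11) * 60.0, pos)
        assert arrest_index(tr) == pytest.approx(0.4)

    def test_stationary_track_is_one(self):
        tr = make_track(np.arange(6) * 37.5, np.zeros((6, 3)))
        assert arrest_index(tr) == 1.0

    def test_duration_weighting_with_irregular_sampling(self):
        # slow interval lasts 3× longer than the fast one
        tr = make_track([0, 180, 240], [[0, 0, 0], [1, 0, 0], [9, 0, 0]])
        assert arrest_index(tr) == pytest.approx(0.75)

    def test_negative_threshold_rejected(self):
        tr = make_track([0, 60], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            arrest_index(tr, threshold=-1.0)

    def test_episode_runs(self):
        steps = [5.0, 1.0, 1.0, 5.0, 1.0]
        pos = np.zeros((6, 3))
        pos[1:, 1] = np.cumsum(steps)
        tr = make_track(np.arange(6) * 60.0, pos)
        assert arrest_episodes(tr) == 2

    def test_ballistic_track_has_no_episodes(self):
        tr = make_track(np.arange(12) * 37.5,
                        np.outer(np.arange(12), [3.0, 0, 0]))
        assert arrest_episodes(tr) == 0

    def test_episodes_match_generator_state_runs(self):
        # well-separated speeds: sub-threshold intervals == arrested states
        params = SyntheticParams(mode="two_state", v_motile_mean=10.0,
                                 v_motile_sd=1.0, v_arrest_mean=0.0,
                                 p_stop=0.3, p_go=0.3, n_tracks=30,
                                 n_points=25, seed=3)
        for tr in generate_cohort(params):
            states = tr.state_sequence
            runs = int(np.sum(~states[1:] & states[:-1]) + (not states[0]))
            assert arrest_episodes(tr) == runs


class TestBruteForceEquivalence:
    def test_all_metrics_match_loop_oracles(self):
        rng = np.random.default_rng(123)
        for tr in random_tracks(200, rng):
            t, p = tr.times, tr.positions
            np.testing.assert_allclose(
                instantaneous_speeds(tr), oracles.speeds_loop(t, p),
                rtol=1e-9)
            assert mean_track_velocity(tr) == pytest.approx(
                oracles.mean_velocity_loop(t, p), rel=1e-9)
            assert meandering_index(tr) == pytest.approx(
                oracles.meandering_loop(p), rel=1e-9)
            assert arrest_index(tr) == pytest.approx(
                oracles.arrest_index_loop(t, p), rel=1e-9)
            assert arrest_episodes(tr) == oracles.arrest_episodes_loop(t, p)


@st.composite
def track_strategy(draw):
    n = draw(st.integers(3, 12))
    dts = draw(st.lists(st.floats(10.0, 60.0), min_size=n - 1,
                        max_size=n - 1))
    coords = draw(st.lists(
        st.tuples(*[st.floats(-50, 50, allow_nan=False)] * 3),
        min_size=n, max_size=n))
    times = np.concatenate([[0.0], np.cumsum(dts)])
    return make_track(times, np.array(coords))


class TestMetricInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(track_strategy())
    def test_displacement_bounded_by_path(self, tr):
        from sasmotility.metrics import net_displacement, path_length
        assert net_displacement(tr) <= path_length(tr) + 1e-9
        assert 0.0 <= meandering_index(tr) <= 1.0 + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(track_strategy(), st.integers(0, 1000))
    def test_rigid_motion_invariance(self, tr, seed):
        rng = np.random.default_rng(seed)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-100, 100, 3)
        moved = make_track(tr.times, tr.positions @ q.T + shift)
        assert meandering_index(moved) == pytest.approx(
            meandering_index(tr), rel=1e-6, abs=1e-9)
        assert arrest_index(moved) == pytest.approx(arrest_index(tr),
                                                    abs=1e-9)

    def test_velocity_scales_with_coordinates(self):
        rng = np.random.default_rng(5)
        tr = random_tracks(1, rng)[0]
        scaled = make_track(tr.times, tr.positions * 2.5)
        assert mean_track_velocity(scaled) == pytest.approx(
            2.5 * mean_track_velocity(tr), rel=1e-9)


class TestCurves:
    def test_ballistic_curve_is_v_tau(self):
        v = 5.0  # μm/min
        tr = make_track(np.arange(13) * 37.5,
                        np.outer(np.arange(13) * 37.5 / 60 * v, [1., 0, 0]))
        c = displacement_curve([tr], grid_step=37.5)
        np.testing.assert_allclose(c.mean, v * c.time_grid / 60.0,
                                   atol=1e-9)
        assert c.mean[0] == 0.0

    def test_msd_examples(self):
        v = 6.0
        tr = make_track(np.arange(10) * 30.0,
                        np.outer(np.arange(10) * 30.0 / 60 * v, [0, 1., 0]))
        c = msd_curve([tr], grid_step=30.0)
        np.testing.assert_allclose(c.mean, (v * c.time_grid / 60.0) ** 2,
                                   rtol=1e-9)
        flat = make_track(np.arange(10) * 30.0, np.zeros((10, 3)))
        np.testing.assert_allclose(msd_curve([flat], 30.0).mean, 0.0)

    def test_track_dropout_makes_n_nonincreasing(self):
        rng = np.random.default_rng(11)
        tracks = random_tracks(20, rng, n_points_range=(5, 25))
        c = displacement_curve(tracks, grid_step=40.0)
        assert np.all(np.diff(c.n_tracks) <= 0)
        assert c.n_tracks[0] == 20

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            displacement_curve([], 37.5)

    def test_cohort_mean_matches_brute_force(self):
        rng = np.random.default_rng(21)
        tracks = random_tracks(50, rng, n_points_range=(8, 12))
        got = metrics_table(tracks)["mean_velocity"].mean()
        want = np.mean([oracles.mean_velocity_loop(t.times, t.positions)
                        for t in tracks])
        assert got == pytest.approx(want, rel=1e-9)


class TestNormalizeTrajectories:
    def test_first_point_at_origin_and_translation_invariance(self):
        rng = np.random.default_rng(31)
        tr = random_tracks(1, rng)[0]
        shifted = make_track(tr.times, tr.positions + [10.0, -5.0, 3.0])
        na = normalize_trajectories([tr])[0]
        nb = normalize_trajectories([shifted])[0]
        np.testing.assert_allclose(na[0], 0.0)
        np.testing.assert_allclose(na, nb, atol=1e-9)

    def test_drift_axis_anisotropy(self):
        params = SyntheticParams(mode="two_state", v_motile_mean=8.0,
                                 v_motile_sd=1.0, p_stop=0.0, p_go=1.0,
                                 kappa=2.0, drift_axis=(0, 1, 0),
                                 drift_bias=0.7, n_tracks=100, n_points=30,
                                 seed=17)
        norm = normalize_trajectories(generate_cohort(params))
        y_ext = np.percentile([np.abs(n[:, 1]).max() for n in norm], 95)
        x_ext = np.percentile([np.abs(n[:, 0]).max() for n in norm], 95)
        assert y_ext > x_ext
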