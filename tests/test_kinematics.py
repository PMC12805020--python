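import math

import numpy as np
import pytest

from surgmotion.kinematics import (
    angular_change,
    avg_acceleration,
    avg_velocity,
    case_metrics,
    grid_workspace_coverage,
    rms_jerk,
    smooth_track,
    step_displacements,
    total_path_length,
    workspace_coverage,
)
from surgmotion.track_io import CaseRecord, InstrumentTrack

from conftest import make_track, random_track
from _oracles import (
    convex_hull_area_brute,
    finite_diff_metrics_brute,
    path_length_brute,
)


def _segment_coords(track):
    return [seg.xy for seg in track.segments]


class TestStepDisplacements:
    def test_simple_segment(self):
        d = step_displacements(make_track([(0, 0), (1, 0), (1, 1)]))
        np.testing.assert_array_equal(d, [[1, 0], [0, 1]])

    def test_no_displacement_across_gap(self):
        track = make_track([(0, 0), (1, 0), (5, 5), (6, 5)], gaps_after=[1])
        d = step_displacements(track)
        assert d.shape == (2, 2)
        np.testing.assert_array_equal(d, [[1, 0], [1, 0]])

    def test_count_equals_sum_of_segment_lengths_minus_one(self, rng):
        for _ in range(10):
            track = random_track(rng, n_points=50, n_gaps=int(rng.integers(0, 5)))
            expected = sum(len(s) - 1 for s in track.segments)
            assert step_displacements(track).shape[0] == expected


class TestPathLength:
    def test_3_4_5_triangle(self):
        assert total_path_length(make_track([(0, 0), (3, 4)])) == 5.0

    def test_three_unit_square_edges(self):
        track = make_track([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert total_path_length(track) == pytest.approx(3.0)

    def test_single_point_is_zero(self):
        assert total_path_length(make_track([(7, 7)])) == 0.0

    def test_matches_brute_force_sum(self, rng):
        for _ in range(20):
            track = random_track(rng, n_points=40, n_gaps=2)
            assert total_path_length(track) == pytest.approx(
                path_length_brute(_segment_coords(track)), rel=1e-12
            )


class TestVelocityAccelerationJerk:
    def test_unit_steps_at_15fps(self):
        track = make_track([(i, 0) for i in range(6)], fps=15)
        assert avg_velocity(track) == pytest.approx(15.0)

    def test_stationary_tip(self):
        assert avg_velocity(make_track([(5, 5)] * 4)) == 0.0

    def test_velocity_nan_without_displacements(self):
        assert math.isnan(avg_velocity(make_track([(1, 2)])))

    def test_constant_velocity_line_has_zero_acceleration_and_jerk(self):
        track = make_track([(i * 3, i * 4) for i in range(8)], fps=15)
        assert avg_acceleration(track) == 0.0
        assert rms_jerk(track) == 0.0

    def test_constant_acceleration_arithmetic(self):
        # x = 0, 1, 3 at 15 fps: v = 15, 30 px/s; a = 225 px/s^2
        track = make_track([(0, 0), (1, 0), (3, 0)], fps=15)
        assert avg_acceleration(track) == pytest.approx(225.0)

    def test_quadratic_positions_have_zero_jerk(self):
        # x = 0, 1, 3, 6: constant second difference => zero jerk
        track = make_track([(0, 0), (1, 0), (3, 0), (6, 0)], fps=15)
        assert rms_jerk(track) == pytest.approx(0.0)

    def test_insufficient_points_are_nan(self):
        two = make_track([(0, 0), (1, 0)])
        assert math.isnan(avg_acceleration(two))
        three = make_track([(0, 0), (1, 0), (3, 0)])
        assert math.isnan(rms_jerk(three))

    def test_matches_finite_difference_oracle(self, rng):
        for _ in range(20):
            track = random_track(rng, n_points=30, n_gaps=1, fps=15)
            expect = finite_diff_metrics_brute(_segment_coords(track), fps=15)
            assert avg_velocity(track) == pytest.approx(expect["avg_velocity"])
            assert avg_acceleration(track) == pytest.approx(expect["avg_acceleration"])
            assert rms_jerk(track) == pytest.approx(expect["rms_jerk"])

    def test_gap_never_bridged_by_derivatives(self):
        """A huge positional jump across a gap must not create velocity."""
        quiet = [(500 + 0.1 * i, 500) for i in range(5)]
        far = [(5000 + 0.1 * i, 500) for i in range(5)]
        track = make_track(quiet + far, gaps_after=[4])
        assert avg_velocity(track) == pytest.approx(0.1 * 15)


class TestAngularChange:
    def test_straight_line_zero(self):
        total, avg = angular_change(make_track([(0, 0), (1, 0), (2, 0)]))
        assert total == 0.0 and avg == 0.0

    def test_right_angle_turn(self):
        _, avg = angular_change(make_track([(0, 0), (1, 0), (1, 1)]))
        assert avg == pytest.approx(90.0)

    def test_full_reversal(self):
        _, avg = angular_change(make_track([(0, 0), (1, 0), (0, 0)]))
        assert avg == pytest.approx(180.0)

    def test_zero_length_steps_skipped(self):
        # the stationary step invalidates its two vertices; the remaining
        # 90-degree turn alone defines the average (not diluted to 30)
        track = make_track([(0, 0), (1, 0), (1, 1), (1, 1), (1, 2)])
        total, avg = angular_change(track)
        assert total == pytest.approx(90.0)
        assert avg == pytest.approx(90.0)

    def test_all_steps_zero_length_is_undefined(self):
        total, avg = angular_change(make_track([(1, 0), (1, 0), (1, 0)]))
        assert math.isnan(total) and math.isnan(avg)

    def test_nan_without_valid_vertex(self):
        total, avg = angular_change(make_track([(0, 0), (1, 1)]))
        assert math.isnan(total) and math.isnan(avg)

    def test_total_is_sum_average_is_mean(self):
        track = make_track([(0, 0), (1, 0), (1, 1), (0, 1)])
        total, avg = angular_change(track)
        assert total == pytest.approx(180.0)
        assert avg == pytest.approx(90.0)


class TestWorkspace:
    def test_right_triangle(self):
        assert workspace_coverage(make_track([(0, 0), (4, 0), (0, 3)])) == pytest.approx(6.0)

    def test_unit_square(self):
        track = make_track([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert workspace_coverage(track) == pytest.approx(1.0)

    def test_collinear_and_tiny_clouds_are_zero(self):
        assert workspace_coverage(make_track([(0, 0), (1, 1), (2, 2)])) == 0.0
        assert workspace_coverage(make_track([(0, 0), (1, 1)])) == 0.0

    def test_matches_brute_force_hull(self, rng):
        for _ in range(20):
            track = random_track(rng, n_points=40, n_gaps=2)
            expected = convex_hull_area_brute(track.all_xy())
            assert workspace_coverage(track) == pytest.approx(expected, rel=1e-9)

    def test_grid_alternative_counts_cells(self):
        track = make_track([(0, 0), (0, 1), (25, 1)])
        assert grid_workspace_coverage(track, cell=10.0) == 200.0  # 2 cells


class TestCaseMetrics:
    def test_l_shaped_track(self, l_track):
        rec = CaseRecord(case_number=5, video_index=1, tracks=[l_track])
        (m,) = case_metrics(rec)
        assert m.path_length == pytest.approx(2.0)
        assert m.avg_angular_change == pytest.approx(90.0)
        assert m.workspace_coverage == pytest.approx(0.5)
        assert m.n_points == 3 and m.n_segments == 1

    def test_no_tracks_gives_empty_list(self):
        assert case_metrics(CaseRecord(case_number=5, video_index=1)) == []


def _transform_track(track, fn):
    from surgmotion.track_io import TrackSegment
    segs = [TrackSegment(s.frames.copy(), fn(s.xy)) for s in track.segments]
    return InstrumentTrack(instrument=track.instrument, segments=segs,
                           fps=track.fps)


def _all_metrics(track):
    _, avg_ang = angular_change(track)
    return np.array([
        total_path_length(track), avg_velocity(track),
        avg_acceleration(track), rms_jerk(track),
        avg_ang, workspace_coverage(track),
    ])


class TestInvariances:
    N_TRACKS = 50

    def test_translation_invariance(self, rng):
        for _ in range(self.N_TRACKS):
            track = random_track(rng, n_points=25, n_gaps=1)
            shift = rng.normal(0, 100, size=2)
            moved = _transform_track(track, lambda xy: xy + shift)
            np.testing.assert_allclose(_all_metrics(moved), _all_metrics(track),
                                       rtol=1e-8, atol=1e-8)

    def test_rotation_invariance(self, rng):
        for _ in range(self.N_TRACKS):
            track = random_track(rng, n_points=25, n_gaps=1)
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            rotated = _transform_track(track, lambda xy: xy @ R.T)
            np.testing.assert_allclose(_all_metrics(rotated), _all_metrics(track),
                                       rtol=1e-7, atol=1e-7)

    def test_scaling_covariance(self, rng):
        for _ in range(self.N_TRACKS):
            track = random_track(rng, n_points=25, n_gaps=1)
            s = float(rng.uniform(0.5, 3.0))
            scaled = _transform_track(track, lambda xy: xy * s)
            base = _all_metrics(track)
            expect = base * np.array([s, s, s, s, 1.0, s * s])
            np.testing.assert_allclose(_all_metrics(scaled), expect,
                                       rtol=1e-8, atol=1e-8)

    def test_fps_scaling(self, rng):
        for _ in range(self.N_TRACKS):
            track = random_track(rng, n_points=25, n_gaps=1, fps=15)
            doubled = InstrumentTrack(
                instrument=track.instrument,
                segments=track.segments, fps=30,
            )
            base = _all_metrics(track)
            expect = base * np.array([1.0, 2.0, 4.0, 8.0, 1.0, 1.0])
            np.testing.assert_allclose(_all_metrics(doubled), expect,
                                       rtol=1e-9, atol=1e-9)


class TestSmoothing:
    def test_line_is_fixed_point(self):
        track = make_track([(i, 2 * i) for i in range(10)])
        sm = smooth_track(track, window=3)
        np.testing.assert_allclose(sm.segments[0].xy,
                                   track.segments[0].xy[1:-1])

    def test_short_segments_pass_through(self):
        track = make_track([(0, 0), (1, 1)])
        sm = smooth_track(track, window=5)
        np.testing.assert_array_equal(sm.segments[0].xy, track.segments[0].xy)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(make_track([(0, 0)]), window=4)
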