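"""Velocity, acceleration, the MF1 motion series, and segment detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import posemotion as pm

from conftest import make_sequence, random_sequence


def loop_velocity(seq):
    """Independent naive reference: explicit per-point, per-frame loop."""
    dt = 1.0 / seq.fps
    vx = np.empty((seq.n_frames - 1, seq.n_points))
    vy = np.empty_like(vx)
    for t in range(seq.n_frames - 1):
        for i in range(seq.n_points):
            vx[t, i] = (seq.x[t + 1, i] - seq.x[t, i]) / dt
            vy[t, i] = (seq.y[t + 1, i] - seq.y[t, i]) / dt
    return vx, vy


def loop_mf1(vx, vy):
    out = []
    for t in range(vx.shape[0]):
        sx = sum(vx[t])
        sy = sum(vy[t])
        out.append((sx**2 + sy**2) ** 0.5)
    return np.array(out)


class TestVelocity:
    def test_static_sequence_is_exactly_zero(self):
        x = np.full((10, 25), 300.0)
        v = pm.velocity(make_sequence(x, x))
        assert not v.vx.any() and not v.vy.any()
        assert v.vx.shape == (9, 25)

    def test_ten_pixels_per_frame_at_25fps_is_250(self):
        x = np.array([[0.0], [10.0]])
        model = pm.KeypointModelSpec("p1", 1, ("only",), "pose_keypoints_2d")
        v = pm.velocity(make_sequence(x, x * 0, model=model, fps=25))
        assert v.vx[0, 0] == 250.0
        assert v.vy[0, 0] == 0.0

    def test_matches_naive_loop(self, rng):
        seq = random_sequence(rng, 10, n_points=25)
        v = pm.velocity(seq)
        vx, vy = loop_velocity(seq)
        np.testing.assert_allclose(v.vx, vx, atol=1e-12)
        np.testing.assert_allclose(v.vy, vy, atol=1e-12)

    def test_needs_two_frames(self):
        x = np.zeros((1, 25))
        with pytest.raises(ValueError, match="at least 2"):
            pm.velocity(make_sequence(x, x))


class TestAcceleration:
    def test_constant_velocity_has_zero_acceleration(self):
        t = np.arange(10, dtype=float)
        x = np.tile((5 * t)[:, None], (1, 25))
        a = pm.acceleration(make_sequence(x, x))
        np.testing.assert_allclose(a.ax, 0, atol=1e-9)
        np.testing.assert_allclose(a.ay, 0, atol=1e-9)
        assert a.ax.shape == (8, 25)

    def test_quadratic_position_gives_constant_acceleration(self):
        # x = t^2 at 1 fps: second difference is exactly 2 px/s^2
        t = np.arange(8, dtype=float)
        model = pm.KeypointModelSpec("p1", 1, ("only",), "pose_keypoints_2d")
        x = (t**2)[:, None]
        a = pm.acceleration(make_sequence(x, x * 0, model=model, fps=1))
        np.testing.assert_allclose(a.ax, 2.0, atol=1e-12)

    def test_needs_three_frames(self):
        x = np.zeros((2, 25))
        with pytest.raises(ValueError, match="at least 3"):
            pm.acceleration(make_sequence(x, x))


class TestEuclideanNormOfSums:
    def test_three_four_five(self):
        v = pm.VelocityField(
            vx=np.array([[3.0, 0.0]]), vy=np.array([[0.0, 4.0]]), fps=25
        )
        assert pm.euclidean_norm_of_sums(v).values[0] == 5.0

    def test_opposite_velocities_cancel_before_norm(self):
        v = pm.VelocityField(
            vx=np.array([[7.0, -7.0]]), vy=np.array([[2.5, -2.5]]), fps=25
        )
        assert pm.euclidean_norm_of_sums(v).values[0] == 0.0
        # the sum-of-norms variant does not cancel
        assert pm.sum_of_norms(v).values[0] == pytest.approx(
            2 * np.hypot(7.0, 2.5)
        )

    def test_rigid_translation_closed_form(self):
        # all N points share (dx, dy) per frame -> MF1 = N * fps * ||d||
        n_frames, fps, dx = 6, 25.0, 1.0
        t = np.arange(n_frames, dtype=float)
        x = np.tile((dx * t)[:, None], (1, 25)) + np.arange(25)
        y = np.full_like(x, 200.0)
        series = pm.motion_series(make_sequence(x, y, fps=fps))
        np.testing.assert_allclose(series.values, 25 * fps * dx, atol=1e-9)

    def test_values_are_nonnegative(self, rng):
        series = pm.motion_series(random_sequence(rng, 30))
        assert (series.values >= 0).all()

    def test_triangle_inequality_vs_sum_of_norms(self, rng):
        seq = random_sequence(rng, 40)
        v = pm.velocity(seq)
        mf1 = pm.euclidean_norm_of_sums(v).values
        upper = pm.sum_of_norms(v).values
        assert (mf1 <= upper + 1e-9).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            pm.VelocityField(vx=np.zeros((3, 2)), vy=np.zeros((2, 2)), fps=25)


class TestInvariants:
    @given(seed=st.integers(0, 2**31 - 1))
    def test_oracle_equivalence(self, seed):
        """Vectorized kinematics equal the naive loop on random sequences."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        seq = random_sequence(rng, n)
        v = pm.velocity(seq)
        vx, vy = loop_velocity(seq)
        np.testing.assert_allclose(v.vx, vx, atol=1e-9)
        np.testing.assert_allclose(
            pm.euclidean_norm_of_sums(v).values, loop_mf1(vx, vy), atol=1e-9
        )

    def test_framerate_scaling_doubles_velocity_and_mf1(self, rng):
        x = rng.uniform(0, 640, (20, 25))
        y = rng.uniform(0, 480, (20, 25))
        s25 = make_sequence(x, y, fps=25)
        s50 = make_sequence(x, y, fps=50)
        np.testing.assert_array_equal(
            pm.velocity(s50).vx, 2 * pm.velocity(s25).vx
        )
        np.testing.assert_array_equal(
            pm.motion_series(s50).values, 2 * pm.motion_series(s25).values
        )

    def test_time_reversal_negates_velocity_and_reverses_mf1(self, rng):
        seq = random_sequence(rng, 15)
        rev = pm.PoseSequence(
            seq.model, seq.x[::-1], seq.y[::-1], seq.c[::-1], fps=seq.fps
        )
        np.testing.assert_allclose(
            pm.velocity(rev).vx, -pm.velocity(seq).vx[::-1], atol=1e-12
        )
        np.testing.assert_allclose(
            pm.motion_series(rev).values,
            pm.motion_series(seq).values[::-1],
            atol=1e-9,
        )


class TestSummaryAndSegments:
    def test_all_zero_series_summary(self):
        s = pm.MotionSeries(np.zeros(5), "velocity", 25)
        summary = pm.summarize_clip(s)
        assert (summary.total, summary.mean, summary.peak) == (0, 0, 0)
        assert summary.peak_transition == 0

    def test_simple_summary(self):
        s = pm.MotionSeries(np.array([1.0, 2.0, 3.0]), "velocity", 25)
        summary = pm.summarize_clip(s)
        assert summary.total == 6 and summary.mean == 2
        assert summary.peak == 3 and summary.peak_transition == 2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pm.summarize_clip(pm.MotionSeries(np.array([]), "velocity", 25))

    def test_all_zero_series_has_no_segments(self):
        s = pm.MotionSeries(np.zeros(7), "velocity", 25)
        assert pm.detect_motion_segments(s) == []

    def test_single_burst_segment(self):
        s = pm.MotionSeries(
            np.array([0, 0, 5, 6, 5, 0, 0], dtype=float), "velocity", 25
        )
        assert pm.detect_motion_segments(s, 0.5, 1) == [(2, 4)]

    def test_two_separated_bursts(self):
        values = np.zeros(40)
        values[5:10] = 10
        values[28:34] = 8
        s = pm.MotionSeries(values, "velocity", 25)
        assert pm.detect_motion_segments(s, 0.1, 3) == [(5, 9), (28, 33)]

    def test_close_bursts_merge(self):
        values = np.zeros(20)
        values[4:7] = 10
        values[8:11] = 10  # 1-transition gap < min_len=3
        s = pm.MotionSeries(values, "velocity", 25)
        assert pm.detect_motion_segments(s, 0.1, 3) == [(4, 10)]

    def test_burst_fixture_peak_inside_burst(self):
        spec = pm.TrajectorySpec(
            n_frames=60,
            programs={4: pm.MotionProgram("burst", start=20, length=15,
                                          amplitude=40.0)},
        )
        _, truth = pm.generate(spec)
        peak = int(truth.mf1_velocity.argmax())
        assert 20 <= peak < 35

    def test_times_span_clip_duration(self):
        x = np.zeros((125, 25))
        series = pm.motion_series(make_sequence(x, x, fps=25))
        assert len(series) == 124
        assert series.times[0] == pytest.approx(0.04)
        assert series.times[-1] == pytest.approx(4.96)
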