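"""Kinematics: closed-form anchors, equivariances, peak counting."""

import numpy as np
import pytest

from cardiophen.errors import InsufficientDataError, NonUniformSamplingError
from cardiophen.kinematics import (
    TrajectorySet,
    compute_chronotropy,
    compute_displacement,
    compute_velocity_acceleration,
    read_trajectories,
    summarize_kinematics,
    write_trajectories,
)
from cardiophen.synthetic import BeatSpec, make_beat_trajectories


def _single_marker(xy: np.ndarray, fps: float) -> TrajectorySet:
    return TrajectorySet(positions=xy[None, :, :], fps=fps)


class TestDisplacement:
    def test_stationary_marker_is_zero(self):
        traj = _single_marker(np.full((100, 2), 5.0), fps=30)
        assert np.all(compute_displacement(traj) == 0)

    def test_axis_sinusoid_gives_abs_sin(self):
        t = np.arange(300) / 30.0
        xy = np.stack([10.0 + np.sin(2 * np.pi * t), np.full_like(t, 3.0)], axis=1)
        disp = compute_displacement(_single_marker(xy, fps=30))[0]
        np.testing.assert_allclose(disp, np.abs(np.sin(2 * np.pi * t)), atol=1e-12)

    def test_circular_motion_constant_radius_about_mean(self):
        t = np.arange(400) / 100.0
        r = 2.5
        xy = np.stack([r * np.cos(2 * np.pi * t), r * np.sin(2 * np.pi * t)], axis=1)
        disp = compute_displacement(_single_marker(xy, fps=100), rest="mean")[0]
        np.testing.assert_allclose(disp, r, rtol=1e-10)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_displacement(_single_marker(np.zeros((2, 2)), fps=30))


class TestChronotropy:
    def test_sinusoid_frequency_recovered(self):
        traj, _ = make_beat_trajectories(
            BeatSpec(beat_frequency=1.5, fps=30, duration=10, jitter_sd=0.0)
        )
        assert compute_chronotropy(traj) == pytest.approx(1.5, rel=0.02)

    def test_zero_amplitude_gives_zero_with_warning(self):
        traj, _ = make_beat_trajectories(BeatSpec(displacement_amplitude=0.0))
        with pytest.warns(UserWarning):
            assert compute_chronotropy(traj) == 0.0

    def test_pulse_train_counts_beats(self):
        traj, _ = make_beat_trajectories(
            BeatSpec(waveform="pulse-train", beat_frequency=0.5, duration=10)
        )
        assert compute_chronotropy(traj) == pytest.approx(0.5, rel=0.02)

    @pytest.mark.parametrize("f", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("fps", [15.0, 30.0])
    def test_frequency_recovery_grid_with_jitter(self, f, fps):
        traj, _ = make_beat_trajectories(
            BeatSpec(beat_frequency=f, fps=fps, duration=10, jitter_sd=0.1, seed=2)
        )
        assert compute_chronotropy(traj) == pytest.approx(f, rel=0.02)


class TestVelocityAcceleration:
    def test_uniform_drift(self):
        t = np.arange(100) / 10.0
        xy = np.stack([t, np.zeros_like(t)], axis=1)  # 1 px/s along x
        speed, accel = compute_velocity_acceleration(_single_marker(xy, fps=10))
        np.testing.assert_allclose(speed[0], 1.0, atol=1e-9)
        np.testing.assert_allclose(accel[0, 2:-2], 0.0, atol=1e-9)

    def test_sinusoid_maxima_near_closed_form(self):
        traj, _ = make_beat_trajectories(
            BeatSpec(beat_frequency=1.0, displacement_amplitude=1.0, fps=200,
                     jitter_sd=0.0)
        )
        speed, accel = compute_velocity_acceleration(traj)
        assert speed.max() == pytest.approx(2 * np.pi, rel=0.01)
        assert accel.max() == pytest.approx((2 * np.pi) ** 2, rel=0.01)

    def test_amplitude_linearity(self):
        s1, a1 = compute_velocity_acceleration(
            make_beat_trajectories(BeatSpec(displacement_amplitude=1.0))[0]
        )
        s2, a2 = compute_velocity_acceleration(
            make_beat_trajectories(BeatSpec(displacement_amplitude=2.0))[0]
        )
        assert s2.max() == pytest.approx(2 * s1.max(), rel=1e-9)
        assert a2.max() == pytest.approx(2 * a1.max(), rel=1e-9)

    def test_nonuniform_time_base_rejected(self):
        t = np.array([0.0, 0.1, 0.2, 0.5, 0.6, 0.7])
        traj = TrajectorySet(positions=np.zeros((1, 6, 2)), fps=10, times=t)
        with pytest.raises(NonUniformSamplingError):
            compute_velocity_acceleration(traj)


class TestSummary:
    def test_sinusoid_ergotropy(self, sinusoid_recording):
        traj, _ = sinusoid_recording
        summary = summarize_kinematics(traj)
        assert summary.ergotropy == pytest.approx((2 * np.pi) ** 2 / 4, rel=0.02)

    def test_stationary_recording_all_zero(self):
        traj = TrajectorySet(positions=np.ones((3, 100, 2)), fps=30)
        with pytest.warns(UserWarning):
            summary = summarize_kinematics(traj)
        assert summary.chronotropy == 0.0
        assert summary.kinematic_inotropy == 0.0
        assert summary.dynamic_inotropy == 0.0
        assert summary.ergotropy == 0.0

    def test_two_marker_median_is_midpoint(self):
        t = np.arange(300) / 30.0
        s = np.sin(2 * np.pi * t)
        positions = np.zeros((2, 300, 2))
        positions[0, :, 0] = 1.0 * s
        positions[1, :, 0] = 3.0 * s
        summary = summarize_kinematics(TrajectorySet(positions=positions, fps=30))
        # median of per-marker maxima {2pi, 6pi} = 4pi
        assert summary.kinematic_inotropy == pytest.approx(4 * np.pi, rel=0.01)

    def test_scale_equivariance(self, sinusoid_recording):
        traj, _ = sinusoid_recording
        c = 3.7
        base = summarize_kinematics(traj)
        scaled = summarize_kinematics(traj.scaled(c))
        assert scaled.chronotropy == pytest.approx(base.chronotropy, rel=1e-12)
        assert scaled.kinematic_inotropy == pytest.approx(c * base.kinematic_inotropy, rel=1e-9)
        assert scaled.dynamic_inotropy == pytest.approx(c * base.dynamic_inotropy, rel=1e-9)
        assert scaled.ergotropy == pytest.approx(c**2 * base.ergotropy, rel=1e-9)

    def test_time_reversal_invariance(self, sinusoid_recording):
        traj, _ = sinusoid_recording
        fwd = summarize_kinematics(traj)
        rev = summarize_kinematics(traj.reversed())
        assert rev.chronotropy == pytest.approx(fwd.chronotropy, rel=0.02)
        assert rev.kinematic_inotropy == pytest.approx(fwd.kinematic_inotropy, rel=1e-6)
        assert rev.dynamic_inotropy == pytest.approx(fwd.dynamic_inotropy, rel=1e-6)
        assert rev.ergotropy == pytest.approx(fwd.ergotropy, rel=1e-6)


class TestIO:
    def test_csv_round_trip(self, tmp_path, sinusoid_recording):
        traj, _ = sinusoid_recording
        path = tmp_path / "traj.csv"
        write_trajectories(traj, path, pixel_size=0.1)
        loaded = read_trajectories(path)
        assert loaded.fps == traj.fps
        np.testing.assert_allclose(loaded.positions, traj.positions)
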