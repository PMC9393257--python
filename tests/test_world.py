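"""Target motion, duty cycle, and binaural phase geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmodal.agent import Pose
from crossmodal.world import (
    AcousticParams,
    SoundSchedule,
    TargetState,
    TrajectorySchedule,
    emit_binaural,
    equivalent_peak_frequency,
    generate_trajectory,
    phase_difference,
    sound_duty_schedule,
    step_target,
    wavelength,
)


class TestPhaseDifference:
    @pytest.mark.parametrize(
        "f,d,theta_deg,expected",
        [
            (1500.0, 0.013, 90.0, 0.36036),
            (1500.0, 0.013, -90.0, -0.36036),
            (2200.0, 0.013, 30.0, 0.2643),
            (2200.0, 0.013, 0.0, 0.0),
        ],
    )
    def test_known_values(self, f, d, theta_deg, expected):
        dphi = phase_difference(f, d, math.radians(theta_deg), 340.0)
        assert dphi == pytest.approx(expected, abs=5e-5)

    @given(theta=st.floats(-math.pi / 2, math.pi / 2), f=st.floats(100.0, 5000.0))
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetric_and_bounded(self, theta, f):
        d, c = 0.013, 340.0
        assert phase_difference(f, d, -theta, c) == pytest.approx(
            -phase_difference(f, d, theta, c), abs=1e-12
        )
        assert abs(phase_difference(f, d, theta, c)) <= 2 * math.pi * f * d / c + 1e-12

    def test_equivalent_frequency_for_wider_separation(self):
        # a 100 mm separation needs a 0.195 kHz tone for the same peak phase
        assert equivalent_peak_frequency(0.1) == pytest.approx(195.0, abs=1e-9)
        dphi_ref = phase_difference(1500.0, 0.013, math.pi / 2)
        dphi_wide = phase_difference(195.0, 0.1, math.pi / 2)
        assert dphi_wide == pytest.approx(dphi_ref, rel=1e-12)

    def test_wavelength_passband_endpoints(self):
        assert wavelength(1000.0) == pytest.approx(0.340)
        assert wavelength(4000.0) == pytest.approx(0.085)


class TestTrajectory:
    def test_invariants_over_seeds(self):
        for seed in range(10):
            sched = generate_trajectory(100, np.random.default_rng(seed))
            assert sched.n_steps >= 100
            assert all(0.0 <= s <= 10.0 for s, _ in sched.along)
            assert all(5 <= h <= 10 for _, h in sched.along)
            assert all(0.0 <= s <= 4.0 for s, _ in sched.cross)
            assert all(0 <= h <= 5 for _, h in sched.cross)
            assert all(g in (-1, 1) for g in sched.cross_signs)
            assert sched.direction == (-1.0, 0.0)

    def test_minimal_length(self):
        sched = generate_trajectory(1, np.random.default_rng(0))
        assert len(sched.along) >= 1 and sched.n_steps >= 1

    def test_along_speed_mean_matches_uniform_moments(self):
        # along-track speeds are U[0, 10]: mean 5, sd 10/sqrt(12)
        sched = generate_trajectory(10_000, np.random.default_rng(1))
        speeds = np.repeat([s for s, _ in sched.along], [h for _, h in sched.along])
        n_seg = len(sched.along)
        se = (10 / math.sqrt(12)) / math.sqrt(n_seg)
        assert abs(np.mean([s for s, _ in sched.along]) - 5.0) < 3 * se
        assert speeds.min() >= 0 and speeds.max() <= 10

    def test_rejects_nonpositive_steps(self):
        with pytest.raises(ValueError):
            generate_trajectory(0, np.random.default_rng(0))


class TestDutyCycle:
    def test_interval_ranges(self):
        sched = sound_duty_schedule(50, np.random.default_rng(3))
        assert all(5 <= off <= 10 and 10 <= on <= 15 for off, on in sched.intervals)

    def test_minimal_case_has_one_pair(self):
        sched = sound_duty_schedule(5, np.random.default_rng(0))
        assert len(sched.intervals) >= 1
        assert not sched.sound_on(0)  # emission starts in an off interval

    def test_on_fraction_matches_expected_interval_lengths(self):
        # E[on]/E[off+on] = 12.5 / 20 = 0.625
        sched = sound_duty_schedule(100_000, np.random.default_rng(2))
        frac = np.mean([sched.sound_on(t) for t in range(100_000)])
        assert frac == pytest.approx(0.625, abs=0.01)


class TestStepTarget:
    @staticmethod
    def _schedules(along, cross, sign=1):
        traj = TrajectorySchedule(
            along=[(along, 10)], cross=[(cross, 5), (cross, 5)], cross_signs=[sign, sign]
        )
        sound = SoundSchedule(intervals=[(5, 10)])
        return traj, sound

    def test_zero_velocity_keeps_position(self):
        traj, sound = self._schedules(0.0, 0.0)
        s0 = TargetState(position=(1.0, 2.0), sound_on=False, t=0)
        s1 = step_target(s0, traj, sound)
        assert s1.position == (1.0, 2.0) and s1.t == 1

    def test_along_track_displacement_is_right_to_left(self):
        traj, sound = self._schedules(2.0, 0.0)
        s0 = TargetState(position=(0.0, 0.0), sound_on=False, t=0)
        s1 = step_target(s0, traj, sound)
        assert s1.position[0] == pytest.approx(-2.0)
        assert s1.position[1] == pytest.approx(0.0)

    def test_speed_scale_scales_displacement(self):
        traj, sound = self._schedules(2.0, 1.0, sign=-1)
        s0 = TargetState(position=(0.0, 0.0), sound_on=False, t=0)
        s1 = step_target(s0, traj, sound, speed_scale=0.5)
        assert s1.position[0] == pytest.approx(-1.0)
        assert abs(s1.position[1]) == pytest.approx(0.5)

    def test_sound_flag_follows_schedule(self):
        traj, sound = self._schedules(1.0, 0.0)
        s = TargetState(position=(0.0, 0.0), sound_on=False, t=0)
        for _ in range(8):
            s = step_target(s, traj, sound)
        assert s.sound_on == sound.sound_on(s.t)

    def test_out_of_range_step_raises(self):
        traj, sound = self._schedules(1.0, 0.0)
        s = TargetState(position=(0.0, 0.0), sound_on=False, t=99)
        with pytest.raises(IndexError):
            step_target(s, traj, sound)


class TestEmitBinaural:
    def test_silent_while_emission_off(self, acoustics):
        state = TargetState(position=(1.0, 1.0), sound_on=False, t=0)
        sig = emit_binaural(state, Pose(), acoustics)
        assert sig.is_silent and len(sig.left) == acoustics.window

    def test_centered_target_gives_identical_channels(self, acoustics):
        pose = Pose(0.0, 0.0, math.pi / 2)
        state = TargetState(position=(0.0, 2.0), sound_on=True, t=0)
        sig = emit_binaural(state, pose, acoustics)
        np.testing.assert_allclose(sig.left, sig.right)

    @pytest.mark.parametrize("theta_deg", [-90.0, -30.0, 15.0, 60.0, 90.0])
    def test_measured_phase_offset_equals_formula(self, theta_deg):
        # demodulate each channel at the tone frequency and compare phases
        th = math.radians(theta_deg)
        params = AcousticParams(window=4096)  # long window limits leakage bias
        pose = Pose(0.0, 0.0, math.pi / 2)
        state = TargetState(position=(math.sin(th), math.cos(th)), sound_on=True, t=0)
        sig = emit_binaural(state, pose, params)
        t = np.arange(params.window) / params.sample_rate
        carrier = np.exp(-2j * math.pi * params.f * t)
        measured = np.angle(np.sum(sig.right * carrier)) - np.angle(
            np.sum(sig.left * carrier)
        )
        expected = phase_difference(params.f, params.d, th, params.c)
        assert measured == pytest.approx(expected, abs=5e-4)

    def test_rear_bearing_clamps_to_lateral_extreme(self, acoustics):
        pose = Pose(0.0, 0.0, math.pi / 2)
        behind = TargetState(position=(1.0, -2.0), sound_on=True, t=0)
        lateral = TargetState(position=(1.0, 0.0), sound_on=True, t=0)
        np.testing.assert_allclose(
            emit_binaural(behind, pose, acoustics).right,
            emit_binaural(lateral, pose, acoustics).right,
        )

    def test_window_must_cover_two_cycles(self):
        with pytest.raises(ValueError):
            AcousticParams(f=100.0, window=512)


def test_schedule_frame_tabulates_path(rng):
    from crossmodal.world import schedule_frame
    traj = generate_trajectory(20, rng)
    sound = sound_duty_schedule(21, rng)
    df = schedule_frame(traj, sound, start=(5.0, 2.5), n_steps=20, speed_scale=0.01)
    assert list(df.columns) == ["t", "x", "y", "sound_on"]
    assert len(df) == 20
    assert df["x"].iloc[-1] < df["x"].iloc[0]  # net right-to-left motion
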