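"""Cardan decomposition, joint/segment angles, velocities, normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitrel as g
from gaitrel.errors import (
    AlignmentError,
    CycleRangeError,
    InsufficientProgressionError,
    ValidationError,
)
from gaitrel.kinematics import progression_frame


def rot_z(deg):
    return g.compose_cardan(0.0, 0.0, deg)


def make_traj(seg_id, rotations, positions, fs=100.0):
    return g.SegmentPoseTrajectory(seg_id, fs, rotations, positions)


def static_traj(seg_id, rotation, position, n=10, fs=100.0):
    return make_traj(seg_id, np.tile(rotation, (n, 1, 1)),
                     np.tile(position, (n, 1)), fs)


class TestCardan:
    def test_identity_gives_zero_angles(self):
        assert np.allclose(g.cardan_angles(np.eye(3)), 0.0)

    def test_single_axis_rotation(self):
        r = g.compose_cardan(30.0, 0.0, 0.0)
        assert np.allclose(g.cardan_angles(r), [30.0, 0.0, 0.0], atol=1e-12)

    def test_composed_rotation_recovered(self):
        # build by explicit multiplication about x, then y, then z
        rx = g.compose_cardan(20.0, 0.0, 0.0)
        ry = g.compose_cardan(0.0, 10.0, 0.0)
        rz = g.compose_cardan(0.0, 0.0, 5.0)
        assert np.allclose(g.cardan_angles(rx @ ry @ rz), [20.0, 10.0, 5.0],
                           atol=1e-10)

    @given(st.tuples(st.floats(-179.0, 179.0), st.floats(-80.0, 80.0),
                     st.floats(-179.0, 179.0)))
    def test_round_trip_away_from_gimbal_lock(self, angles):
        r = g.compose_cardan(*angles)
        assert np.abs(g.compose_cardan(*g.cardan_angles(r)) - r).max() < 1e-9

    def test_gimbal_lock_warns(self):
        r = g.compose_cardan(25.0, 89.7, 0.0)
        with pytest.warns(g.errors.GimbalLockWarning):
            g.cardan_angles(r)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValidationError):
            g.cardan_angles(np.eye(3) * 1.01)


class TestJointAngles:
    def test_identical_poses_give_zero(self):
        traj = static_traj("thigh_R", np.eye(3), [0.0, 0.0, 1.0])
        wf = g.joint_angle_waveform(traj, traj, "R")
        assert np.allclose([wf.x, wf.y, wf.z], 0.0)

    @pytest.mark.parametrize("side,expected", [
        ("R", (10.0, 5.0, 3.0)),
        ("L", (10.0, -5.0, -3.0)),  # frontal/transverse negated on the left
    ])
    def test_known_relative_rotation(self, side, expected):
        base = g.compose_cardan(7.0, -12.0, 40.0)  # arbitrary proximal pose
        rel = g.compose_cardan(10.0, 5.0, 3.0)
        prox = static_traj("thigh", base, [0.0, 0.0, 1.0])
        dist = static_traj("shank", base @ rel, [0.0, 0.0, 0.6])
        wf = g.joint_angle_waveform(prox, dist, side)
        assert np.allclose([wf.x[0], wf.y[0], wf.z[0]], expected, atol=1e-9)

    def test_mismatched_lengths_rejected(self):
        a = static_traj("a", np.eye(3), [0, 0, 0], n=10)
        b = static_traj("b", np.eye(3), [0, 0, 0], n=12)
        with pytest.raises(AlignmentError):
            g.joint_angle_waveform(a, b, "R")

    def test_mirrored_right_processed_as_left_matches(self, noiseless_trial):
        """Reflecting a right-side motion through the sagittal plane and
        processing it as left reproduces the same three components."""
        segs = noiseless_trial[0]
        mirror = np.diag([-1.0, 1.0, 1.0])
        pel, thigh = segs["pelvis"], segs["thigh_R"]
        pel_m = make_traj("pelvis", mirror @ pel.rotations @ mirror,
                          pel.positions @ mirror)
        thigh_m = make_traj("thigh_L", mirror @ thigh.rotations @ mirror,
                            thigh.positions @ mirror)
        wf_r = g.joint_angle_waveform(pel, thigh, "R")
        wf_l = g.joint_angle_waveform(pel_m, thigh_m, "L")
        for plane in ("x", "y", "z"):
            assert np.allclose(wf_l.component(plane), wf_r.component(plane),
                               atol=1e-9)


class TestSegmentAngles:
    def test_aligned_segment_gives_zero(self):
        traj = static_traj("shank_R", np.eye(3), [0, 1, 0.5])
        wf = g.segment_angle_waveform(traj, [0.0, 1.0, 0.0], "R")
        assert np.allclose([wf.x, wf.y, wf.z], 0.0)

    def test_pitch_about_ml_axis(self):
        traj = static_traj("foot_R", g.compose_cardan(15.0, 0.0, 0.0), [0, 0, 0.1])
        wf = g.segment_angle_waveform(traj, [0.0, 1.0, 0.0], "R")
        assert np.allclose([wf.x[0], wf.y[0], wf.z[0]], [15.0, 0.0, 0.0],
                           atol=1e-9)

    def test_invariant_to_walkway_direction(self):
        """Same physical pitch, walkway rotated 90 deg in the floor plane."""
        q = rot_z(90.0)
        traj = static_traj("foot_R", q @ g.compose_cardan(15.0, 0.0, 0.0),
                           [0, 0, 0.1])
        wf = g.segment_angle_waveform(traj, q @ [0.0, 1.0, 0.0], "R")
        assert np.allclose([wf.x[0], wf.y[0], wf.z[0]], [15.0, 0.0, 0.0],
                           atol=1e-9)

    def test_zero_progression_rejected(self):
        traj = static_traj("foot_R", np.eye(3), [0, 0, 0.1])
        with pytest.raises(ValidationError):
            g.segment_angle_waveform(traj, [0.0, 0.0, 0.0], "R")

    def test_whole_trial_rotation_invariance(self, noiseless_trial):
        """Rotating a trial about the vertical axis changes neither joint
        angles (exactly) nor segment angles (progression co-rotates)."""
        segs = noiseless_trial[0]
        q = rot_z(37.0)
        rotated = {
            sid: make_traj(sid, q @ traj.rotations, traj.positions @ q.T)
            for sid, traj in segs.items()
        }
        wf0 = g.joint_angle_waveform(segs["pelvis"], segs["thigh_R"], "R")
        wf1 = g.joint_angle_waveform(rotated["pelvis"], rotated["thigh_R"], "R")
        assert np.abs(wf0.x - wf1.x).max() < 1e-9
        prog0 = g.progression_direction(segs["pelvis"])
        prog1 = g.progression_direction(rotated["pelvis"])
        s0 = g.segment_angle_waveform(segs["shank_R"], prog0, "R")
        s1 = g.segment_angle_waveform(rotated["shank_R"], prog1, "R")
        for plane in ("x", "y", "z"):
            assert np.allclose(s0.component(plane), s1.component(plane), atol=1e-9)


class TestProgression:
    def test_straight_line(self):
        traj = make_traj("pelvis", np.tile(np.eye(3), (2, 1, 1)),
                         [[0, 0, 1], [0, 3, 1]])
        assert np.allclose(g.progression_direction(traj), [0, 1, 0])

    def test_diagonal_normalized(self):
        traj = make_traj("pelvis", np.tile(np.eye(3), (2, 1, 1)),
                         [[0, 0, 1], [3, 3, 1]])
        s = np.sqrt(2) / 2
        assert np.allclose(g.progression_direction(traj), [s, s, 0])

    def test_stationary_pelvis_rejected(self):
        traj = static_traj("pelvis", np.eye(3), [0, 0, 1])
        with pytest.raises(InsufficientProgressionError):
            g.progression_direction(traj)

    def test_frame_is_right_handed(self):
        f = progression_frame([0.0, 1.0, 0.0])
        assert np.allclose(np.cross(f[:, 0], f[:, 1]), f[:, 2])


class TestRelativeVelocity:
    def test_identical_tracks_zero(self):
        track = np.random.default_rng(0).normal(size=(50, 3))
        v = g.relative_velocity(track, track, [0, 1, 0], 100.0)
        assert np.allclose(v, 0.0)

    def test_quadratic_matches_analytic_derivative(self):
        t = np.arange(0, 1.0, 0.01)
        point = np.column_stack([0 * t, t**2, 0 * t])
        ref = np.zeros_like(point)
        v = g.relative_velocity(point, ref, [0, 1, 0], 100.0)
        assert np.abs(v - 2 * t).max() < 1e-3

    def test_linear_ramp_exact_including_endpoints(self):
        t = np.arange(0, 1.0, 0.01)
        point = np.column_stack([0 * t, 1.2 * t, 0 * t])
        v = g.relative_velocity(point, np.zeros_like(point), [0, 1, 0], 100.0)
        assert np.allclose(v, 1.2, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            g.relative_velocity(np.zeros((2, 3)), np.zeros((2, 3)), [0, 1, 0], 100.0)


class TestTimeNormalize:
    def test_constant_waveform(self):
        out = g.time_normalize(np.full(120, 7.0), 100.0, (0.1, 1.1))
        assert out.shape == (101,)
        assert np.allclose(out, 7.0)

    def test_linear_ramp_exact(self):
        t = np.arange(111) / 100.0
        out = g.time_normalize(t / 1.1, 100.0, (0.0, 1.1))
        assert np.allclose(out, np.arange(101) / 100.0, atol=1e-12)

    def test_sine_close_to_analytic(self):
        fs, cycle = 100.0, 1.10
        t = np.arange(0, 1.2, 1 / fs)
        wave = np.sin(2 * np.pi * t / cycle)
        out = g.time_normalize(wave, fs, (0.0, cycle))
        expected = np.sin(2 * np.pi * np.linspace(0, 1, 101))
        assert np.abs(out - expected).max() < 5e-3

    def test_idempotent_on_normalized_cycle(self):
        curve = np.cos(np.linspace(0, 2 * np.pi, 101))
        # a 101-point cycle sampled at 100 Hz spans exactly 1 s
        again = g.time_normalize(curve, 100.0, (0.0, 1.0))
        assert np.allclose(again, curve, atol=1e-12)

    def test_cycle_outside_range_rejected(self):
        with pytest.raises(CycleRangeError):
            g.time_normalize(np.zeros(50), 100.0, (0.0, 1.0))
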