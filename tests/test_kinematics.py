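"""Rotation matrices, helix geometry, rod pose and pattern classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gnrtrack import kinematics as K

ANGLES = st.floats(-10.0, 10.0, allow_nan=False)


@pytest.mark.parametrize("rot", [K.rot_x, K.rot_y, K.rot_z])
@given(a=ANGLES)
@settings(max_examples=50, deadline=None)
def test_rotation_matrices_orthonormal(rot, a):
    m = rot(a)
    assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
    assert np.isclose(np.linalg.det(m), 1.0, atol=1e-12)


def test_rotation_axis_conventions():
    assert np.allclose(K.rot_z(0.0), np.eye(3))
    # right-handed rotation about X maps +Y onto +Z
    assert np.allclose(K.rot_x(np.pi / 2) @ [0, 1, 0], [0, 0, 1], atol=1e-12)


@given(a=ANGLES, b=ANGLES)
@settings(max_examples=50, deadline=None)
def test_rotation_group_property(a, b):
    assert np.allclose(K.rot_z(a) @ K.rot_z(b), K.rot_z(a + b), atol=1e-12)


class TestHelixCenter:
    hp = K.HelixParams(v=500.0, omega_helix=4.0, h=35.0)  # nm/s to match h

    def test_starts_at_top(self):
        assert np.allclose(K.helix_center(0.0, self.hp), [0, 0, 35.0])

    def test_one_period_advances_one_pitch(self):
        period = 2 * np.pi / self.hp.omega_helix
        c = K.helix_center(period, self.hp)
        assert np.allclose(c, [self.hp.v * period, 0, 35.0], atol=1e-9)
        assert np.isclose(self.hp.v * period, 2 * np.pi * self.hp.v / self.hp.omega_helix)

    def test_orbit_radius_invariant(self):
        t = np.linspace(0, 5, 301)
        c = K.helix_center(t, self.hp)
        assert np.allclose(c[:, 1] ** 2 + c[:, 2] ** 2, 35.0**2)

    def test_left_handed_convention(self):
        # positive omega: at the top of the orbit the center moves +Y
        c = K.helix_center(1e-4, self.hp)
        assert c[1] > 0


class TestRodPose:
    hp = K.HelixParams(v=500.0, omega_helix=4.0, h=35.0)

    def test_initial_rod_along_filament_axis(self):
        yr = K.YawRollParams(omega_roll=4.0, omega_yaw=2.0, phi=0.0)
        pose = K.rod_pose(0.0, self.hp, yr)
        assert np.allclose(pose.tip - pose.end, [2 * K.RodGeometry().r, 0, 0])

    def test_center_is_tip_end_midpoint(self):
        yr = K.YawRollParams(omega_roll=4.0, omega_yaw=-2.0, phi=0.7)
        for t in np.linspace(0, 3, 17):
            pose = K.rod_pose(t, self.hp, yr)
            assert np.allclose(pose.tip + pose.end, 2 * pose.center, atol=1e-9)

    def test_center_independent_of_rotation(self):
        t = np.linspace(0, 2, 50)
        a = K.rod_pose(t, self.hp, K.YawRollParams(4.0, 2.0, 0.0))
        b = K.rod_pose(t, self.hp, K.YawRollParams(-1.0, 0.3, 1.2))
        assert np.allclose(a.center, b.center)

    def test_matrix_product_equals_closed_form(self, rng):
        """The explicit R_X R_Y(0) R_Z p0 + helix product and the closed
        trigonometric forms agree to 1e-12 on 1000 random draws."""
        for _ in range(1000):
            hp = K.HelixParams(
                v=rng.uniform(-1000, 1000),
                omega_helix=rng.uniform(-10, 10),
                h=rng.uniform(0, 100),
            )
            yr = K.YawRollParams(
                omega_roll=rng.uniform(-10, 10),
                omega_yaw=rng.uniform(-10, 10),
                phi=rng.uniform(0, np.pi),
            )
            t = rng.uniform(0, 10)
            a = K.rod_pose(t, hp, yr)
            b = K.rod_pose_matrix(t, hp, yr)
            for u, v in ((a.tip, b.tip), (a.center, b.center), (a.end, b.end)):
                assert np.allclose(u, v, atol=1e-9 * max(1.0, np.abs(u).max()))


class TestProjectedAngle:
    def test_at_t0_equals_phi(self):
        yr = K.YawRollParams(4.0, 2.0, phi=0.6)
        ang, ok = K.projected_angle(0.0, yr)
        assert ok and np.isclose(float(ang), 0.6)

    def test_quarter_roll_collapses_to_axis(self):
        # roll angle pi/2 with yaw angle off pi/2: projection along X
        yr = K.YawRollParams(omega_roll=np.pi / 2, omega_yaw=0.3, phi=0.0)
        ang, ok = K.projected_angle(1.0, yr)
        assert ok and np.isclose(float(ang) % np.pi, 0.0, atol=1e-12)

    def test_agrees_with_tangent_form(self):
        yr = K.YawRollParams(4.0, 2.0, phi=0.4)
        t = np.linspace(0.01, 2.9, 500)
        ang, ok = K.projected_angle(t, yr)
        expected = np.arctan(
            np.cos(yr.omega_roll * t) * np.tan(yr.omega_yaw * t + yr.phi)
        ) % np.pi
        good = ok & (np.abs(np.cos(yr.omega_yaw * t + yr.phi)) > 1e-6)
        assert np.allclose(ang[good], expected[good], atol=1e-9)

    def test_net_rotation_is_180_deg_per_helix_period(self):
        """With omega_yaw = omega_helix/2 the unwrapped angle advances
        exactly 180 deg per helix period (and the full rod orientation
        only repeats after two periods)."""
        w = 2 * np.pi  # helix period 1 s
        yr = K.YawRollParams.coupled(w, yaw_sign=1, phi=0.2)
        t = np.linspace(0.0, 1.0, 2000)
        ang, _ = K.projected_angle(t, yr)
        unw = K.unwrap_angles(ang)
        good = ~np.isnan(unw)
        net = unw[good][-1] - unw[good][0]
        assert np.isclose(abs(net), np.pi, atol=1e-6)
        # physically the rod needs two helix periods for a full turn
        yaw_after_two = yr.omega_yaw * 2.0
        assert np.isclose(yaw_after_two, 2 * np.pi)

    def test_rod_along_z_flagged_undefined(self):
        # phi = pi/2 with quarter roll puts the rod along Z at t=1
        yr = K.YawRollParams(omega_roll=np.pi / 2, omega_yaw=0.0, phi=np.pi / 2)
        _, ok = K.projected_angle(1.0, yr)
        assert not ok


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "phi_deg, expected",
        [(0, "counterclockwise"), (45, "oscillatory"),
         (90, "clockwise"), (135, "oscillatory")],
    )
    def test_clockwise_yaw_patterns(self, phi_deg, expected):
        """The apparent polarization-rotation pattern of a clockwise-yawing
        rod flips with the phase angle: ccw at 0, cw at 90, oscillatory
        in between."""
        assert K.classify_pattern(np.deg2rad(phi_deg), yaw_sign=-1) == expected

    @pytest.mark.parametrize("phi_deg", [0, 30, 90, 150])
    def test_yaw_sign_mirrors_pattern(self, phi_deg):
        swap = {"clockwise": "counterclockwise",
                "counterclockwise": "clockwise",
                "oscillatory": "oscillatory"}
        cw = K.classify_pattern(np.deg2rad(phi_deg), yaw_sign=-1)
        ccw = K.classify_pattern(np.deg2rad(phi_deg), yaw_sign=1)
        assert ccw == swap[cw]

    def test_no_yaw_is_never_unidirectional(self):
        """A rod that rolls without yawing (protofilament-tracking
        control) shows periodic, never unidirectional, angle traces."""
        w = 2 * np.pi
        yr = K.YawRollParams(omega_roll=w, omega_yaw=0.0, phi=0.5)
        t = np.linspace(0, 1, 1000)
        ang, ok = K.projected_angle(t, yr)
        unw = K.unwrap_angles(ang)
        good = ~np.isnan(unw)
        net = unw[good][-1] - unw[good][0]
        assert abs(net) < 0.1 * np.pi
        # periodic with the helix period
        a0, _ = K.projected_angle(t, yr)
        a1, _ = K.projected_angle(t + 1.0, yr)
        assert np.allclose(a0[ok], a1[ok], atol=1e-9)


def test_unwrap_minimises_jumps():
    wrapped = np.array([170.0, 175.0, 1.0, 6.0, 11.0])
    unw = np.rad2deg(K.unwrap_angles(np.deg2rad(wrapped)))
    assert np.allclose(unw, [170, 175, 181, 186, 191])


def test_rod_geometry_validation():
    with pytest.raises(ValueError):
        K.RodGeometry(diameter=50.0, length=40.0)
    assert K.RodGeometry().r == 34.0
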