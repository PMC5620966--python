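"""Core rotation machinery: quaternions, axis-angle, Rodrigues, Euler orders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from kneekin.errors import DegenerateGeometryError, InvalidInputError
from kneekin.rotations import (
    ISB_SEQUENCE,
    KNEE_SEQUENCE,
    axis_angle_between,
    compose_euler,
    dcm_to_quat,
    decompose_dcm,
    estimate_orientation,
    quat_to_dcm,
    rodrigues,
    skew,
)

finite_floats = st.floats(-1.0, 1.0, allow_nan=False)
quat_strategy = st.lists(finite_floats, min_size=4, max_size=4).filter(
    lambda q: np.linalg.norm(q) > 1e-3
)
vec_strategy = st.lists(finite_floats, min_size=3, max_size=3).filter(
    lambda v: np.linalg.norm(v) > 1e-3
)


class TestQuatDcm:
    def test_identity(self):
        assert np.allclose(quat_to_dcm([1, 0, 0, 0]), np.eye(3))

    def test_quarter_turn_about_z_maps_x_to_y(self):
        s = np.sqrt(2) / 2
        R = quat_to_dcm([s, 0, 0, s])
        assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            quat_to_dcm([np.nan, 0, 0, 1])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(quat_strategy)
    def test_round_trip_and_orthonormality(self, q):
        q = np.asarray(q) / np.linalg.norm(q)
        R = quat_to_dcm(q)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-10)
        q2 = dcm_to_quat(R)
        assert np.allclose(q2, q, atol=1e-9) or np.allclose(q2, -q, atol=1e-9)


class TestAxisAngleBetween:
    def test_identical_vectors_zero_angle(self):
        aa = axis_angle_between([1, 0, 0], [1, 0, 0])
        assert aa.angle == pytest.approx(0.0)
        assert not aa.defined

    def test_x_to_y_is_quarter_turn_about_z(self):
        aa = axis_angle_between([1, 0, 0], [0, 1, 0])
        assert np.allclose(aa.axis, [0, 0, 1])
        assert aa.angle == pytest.approx(np.pi / 2)

    def test_antiparallel_raises(self):
        with pytest.raises(DegenerateGeometryError):
            axis_angle_between([1, 0, 0], [-1, 0, 0])

    def test_non_unit_rejected(self):
        with pytest.raises(InvalidInputError):
            axis_angle_between([2, 0, 0], [0, 1, 0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(vec_strategy, vec_strategy)
    def test_rotation_carries_u_onto_v(self, u, v):
        u = np.asarray(u) / np.linalg.norm(u)
        v = np.asarray(v) / np.linalg.norm(v)
        if np.linalg.norm(np.cross(u, v)) < 1e-4:
            return  # (anti)parallel region is handled by its own cases
        aa = axis_angle_between(u, v)
        C = rodrigues(aa)
        assert np.allclose(C @ u, v, atol=1e-9)


class TestRodrigues:
    def test_zero_angle_is_identity(self):
        assert np.allclose(rodrigues([0, 0, 1], 0.0), np.eye(3))

    def test_matches_quaternion_route_for_quarter_turn(self):
        s = np.sqrt(2) / 2
        assert np.allclose(rodrigues([0, 0, 1], np.pi / 2), quat_to_dcm([s, 0, 0, s]), atol=1e-12)

    def test_axis_is_fixed_point(self, rng):
        for _ in range(20):
            k = rng.standard_normal(3)
            k /= np.linalg.norm(k)
            th = rng.uniform(0, np.pi)
            C = rodrigues(k, th)
            assert np.allclose(C @ k, k, atol=1e-10)
            assert np.allclose(C @ C.T, np.eye(3), atol=1e-10)

    def test_agrees_with_quaternion_oracle(self, rng):
        # dual-route check: explicit Rodrigues formula vs scipy's quaternion path
        for _ in range(200):
            k = rng.standard_normal(3)
            k /= np.linalg.norm(k)
            th = rng.uniform(0, np.pi)
            assert np.allclose(
                rodrigues(k, th), Rotation.from_rotvec(k * th).as_matrix(), atol=1e-9
            )

    def test_skew_matrix_cross_product(self):
        v, u = np.array([1.0, 2.0, 3.0]), np.array([-0.5, 0.4, 0.1])
        assert np.allclose(skew(v) @ u, np.cross(v, u))


class TestEulerDecomposition:
    def test_identity_gives_zero_angles(self):
        assert np.allclose(decompose_dcm(np.eye(3)), [0, 0, 0])

    @pytest.mark.parametrize("seq", [KNEE_SEQUENCE, ISB_SEQUENCE])
    def test_compose_decompose_round_trip(self, seq):
        angles = np.deg2rad([10.0, 20.0, 30.0])
        R = compose_euler(angles, seq=seq)
        assert np.allclose(decompose_dcm(R, seq=seq), angles, atol=1e-9)

    def test_round_trip_random_rotations(self, rng):
        q = rng.standard_normal((500, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        R = Rotation.from_quat(q).as_matrix()
        back = compose_euler(decompose_dcm(R), seq=KNEE_SEQUENCE)
        assert np.allclose(back, R, atol=1e-9)

    def test_middle_angle_principal_range(self, rng):
        q = rng.standard_normal((200, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        angles = decompose_dcm(Rotation.from_quat(q).as_matrix())
        assert np.all(np.abs(angles[:, 1]) <= np.pi / 2 + 1e-12)

    def test_gimbal_lock_flagged_third_angle_zeroed(self):
        R = compose_euler(np.deg2rad([25.0, 90.0, 40.0]))
        angles, flag = decompose_dcm(R, return_flags=True)
        assert flag
        assert angles[2] == pytest.approx(0.0, abs=1e-12)
        # recomposition still reproduces the rotation (degenerate DOF folded)
        assert np.allclose(compose_euler(angles), R, atol=1e-9)


class TestOrientationFilter:
    def test_constant_yaw_rate_integrates_exactly(self):
        # 90 deg/s about z for one second from identity -> 90 deg yaw
        t = np.arange(0, 1.0 + 1e-9, 1 / 128)
        gyro = np.tile(np.deg2rad([0, 0, 90.0]), (len(t), 1))
        q = estimate_orientation(t, gyro)
        yaw = Rotation.from_quat(q[-1], scalar_first=True).as_euler("zyx", degrees=True)[0]
        assert yaw == pytest.approx(90.0, abs=0.1)

    def test_zero_rate_with_gravity_stays_constant(self):
        t = np.arange(0, 2, 1 / 64)
        gyro = np.zeros((len(t), 3))
        accel = np.tile([0, 0, 9.81], (len(t), 1))
        q = estimate_orientation(t, gyro, accel, acc_gain=1.0)
        assert np.allclose(q, q[0], atol=1e-12)

    def test_constant_bias_drifts_linearly(self):
        bias = np.deg2rad(0.5)  # rad/s about the vertical
        t = np.arange(0, 20, 1 / 64)
        gyro = np.tile([0, 0, bias], (len(t), 1))
        q = estimate_orientation(t, gyro)
        yaw = Rotation.from_quat(q, scalar_first=True).as_euler("zyx", degrees=True)[:, 0]
        # heading error grows at the bias rate
        slope = np.polyfit(t, yaw, 1)[0]
        assert slope == pytest.approx(np.degrees(bias), rel=1e-6)

    def test_tilt_correction_converges_to_gravity(self):
        t = np.arange(0, 10, 1 / 64)
        gyro = np.zeros((len(t), 3))
        accel = np.tile([0, 0, 9.81], (len(t), 1))
        q0 = Rotation.from_euler("x", 20, degrees=True).as_quat(scalar_first=True)
        q = estimate_orientation(t, gyro, accel, q0=q0, acc_gain=2.0)
        r_end = Rotation.from_quat(q[-1], scalar_first=True)
        up_err = np.degrees(
            np.arccos(np.clip(np.dot(r_end.inv().apply([0, 0, 1]), [0, 0, 1]), -1, 1))
        )
        assert up_err < 0.5

    def test_non_uniform_grid_rejected(self):
        t = np.array([0.0, 0.01, 0.05, 0.06])
        with pytest.raises(InvalidInputError):
            estimate_orientation(t, np.zeros((4, 3)))
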