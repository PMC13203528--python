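"""Quaternion algebra and Madgwick filter behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallsense.attitude import (
    DualFrameSequence,
    MadgwickConfig,
    detect_convergence,
    madgwick_step,
    quaternion_multiply,
    quaternion_to_rotation,
    transform_sequence,
)

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def hamilton_matrix(p):
    """Independent 4x4 matrix form of left-multiplication by p."""
    p0, p1, p2, p3 = p
    return np.array([
        [p0, -p1, -p2, -p3],
        [p1, p0, -p3, p2],
        [p2, p3, p0, -p1],
        [p3, -p2, p1, p0],
    ])


def euler_gyro_integrate(q0, w_dps, dt, n_steps):
    """Brute-force gyroscope-only quaternion integration oracle."""
    q = np.asarray(q0, dtype=float).copy()
    for _ in range(n_steps):
        wr = np.deg2rad(w_dps)
        omega = np.array([0.0, wr[0], wr[1], wr[2]])
        q = q + 0.5 * (hamilton_matrix(q) @ omega) * dt
        q = q / np.linalg.norm(q)
    return q


def random_unit_quaternion(rng):
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


class TestQuaternionAlgebra:
    def test_identity_neutral(self, rng):
        q = random_unit_quaternion(rng)
        assert np.allclose(quaternion_multiply(IDENTITY, q), q)
        assert np.allclose(quaternion_multiply(q, IDENTITY), q)

    def test_i_times_j_is_k(self):
        i, j, k = np.eye(4)[1], np.eye(4)[2], np.eye(4)[3]
        assert np.allclose(quaternion_multiply(i, j), k)

    def test_matches_matrix_form_oracle(self, rng):
        for _ in range(50):
            p, q = rng.normal(size=4), rng.normal(size=4)
            assert np.allclose(
                quaternion_multiply(p, q), hamilton_matrix(p) @ q, atol=1e-12)

    def test_norm_multiplicative(self, rng):
        for _ in range(20):
            p, q = rng.normal(size=4), rng.normal(size=4)
            prod = quaternion_multiply(p, q)
            assert np.isclose(np.linalg.norm(prod),
                              np.linalg.norm(p) * np.linalg.norm(q))


class TestRotationMatrix:
    def test_identity(self):
        assert np.allclose(quaternion_to_rotation(IDENTITY), np.eye(3))

    def test_90_degree_roll_maps_y_to_z(self):
        c = np.cos(np.pi / 4)
        R = quaternion_to_rotation([c, c, 0.0, 0.0])
        assert np.allclose(R @ [0, 1, 0], [0, 0, 1], atol=1e-12)

    def test_matches_conjugation_oracle(self, rng):
        for _ in range(30):
            q = random_unit_quaternion(rng)
            R = quaternion_to_rotation(q)
            qc = np.array([q[0], -q[1], -q[2], -q[3]])
            for v in np.eye(3):
                rotated = quaternion_multiply(
                    quaternion_multiply(q, np.concatenate([[0.0], v])), qc)[1:]
                assert np.allclose(R @ v, rotated, atol=1e-12)

    def test_orthonormal_unit_determinant(self, rng):
        for _ in range(30):
            R = quaternion_to_rotation(random_unit_quaternion(rng))
            assert np.abs(R.T @ R - np.eye(3)).max() <= 1e-9
            assert abs(np.linalg.det(R) - 1.0) <= 1e-9

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError):
            quaternion_to_rotation([1.0, 1.0, 0.0, 0.0])


class TestMadgwickStep:
    def test_gravity_fixed_point(self):
        cfg = MadgwickConfig()
        q = madgwick_step(IDENTITY, [0, 0, 1.0], [0, 0, 0], cfg)
        assert np.allclose(q, IDENTITY)

    def test_unit_norm_preserved(self, rng):
        cfg = MadgwickConfig()
        q = IDENTITY.copy()
        for _ in range(200):
            q = madgwick_step(q, rng.normal(size=3), rng.normal(size=3) * 50, cfg)
            assert abs(np.linalg.norm(q) - 1.0) <= 1e-9

    def test_beta_zero_matches_closed_form_rotation(self):
        # 1 rad/s about z for 10 s -> axis-angle quaternion [cos 5, 0, 0, sin 5]
        cfg = MadgwickConfig(beta=0.0)
        w = np.array([0.0, 0.0, np.degrees(1.0)])
        q = IDENTITY.copy()
        for _ in range(1000):
            q = madgwick_step(q, np.zeros(3), w, cfg)
        expected = np.array([np.cos(5.0), 0.0, 0.0, np.sin(5.0)])
        assert np.linalg.norm(q - expected) <= 1e-2

    def test_beta_zero_matches_euler_integrator_oracle(self, rng):
        cfg = MadgwickConfig(beta=0.0)
        w = rng.normal(size=3) * 80
        q = IDENTITY.copy()
        for _ in range(100):
            q = madgwick_step(q, np.zeros(3), w, cfg)
        oracle = euler_gyro_integrate(IDENTITY, w, cfg.dt, 100)
        assert np.allclose(q, oracle, atol=1e-12)

    def test_free_fall_gating_bit_for_bit(self, rng):
        # below the epsilon gate the fused update equals the gyro-only update
        cfg = MadgwickConfig(beta=0.1)
        cfg0 = MadgwickConfig(beta=0.0)
        q = random_unit_quaternion(rng)
        a_small = rng.normal(size=3) * 0.02  # |a| << 0.1 g
        w = rng.normal(size=3) * 30
        assert np.array_equal(madgwick_step(q, a_small, w, cfg),
                              madgwick_step(q, a_small, w, cfg0))

    def test_static_tilt_converges(self):
        # 30 deg tilt, beta=0.1: predicted gravity reaches the measured
        # direction within 0.5 degrees in under 10 s of samples
        cfg = MadgwickConfig()
        tilt = np.radians(30.0)
        a = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        q = IDENTITY.copy()
        for _ in range(1000):
            q = madgwick_step(q, a, np.zeros(3), cfg)
        g_pred = quaternion_to_rotation(q).T @ np.array([0, 0, 1.0])
        angle = np.degrees(np.arccos(np.clip(g_pred @ a, -1, 1)))
        assert angle < 0.5


class TestTransformSequence:
    def test_static_identity_orientation_passthrough(self):
        ab = np.tile([0.0, 0.0, 1.0], (300, 1))
        wb = np.zeros((300, 3))
        seq = transform_sequence(ab, wb)
        assert np.allclose(seq.a_global, ab, atol=1e-9)

    def test_static_tilt_aligns_gravity(self):
        # 35 deg compound tilt: after convergence the global acceleration
        # points within 0.5 deg of vertical
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("XY", [20, 28.7], degrees=True).as_matrix()
        a = R.T @ np.array([0, 0, 1.0])
        seq = transform_sequence(np.tile(a, (1200, 1)), np.zeros((1200, 3)))
        ag = seq.a_global[-1]
        angle = np.degrees(np.arccos(ag[2] / np.linalg.norm(ag)))
        assert angle < 0.5

    def test_isometry_per_sample(self, rng):
        ab = rng.normal(size=(150, 3))
        wb = rng.normal(size=(150, 3)) * 40
        seq = transform_sequence(ab, wb)
        assert np.allclose(np.linalg.norm(seq.a_global, axis=1),
                           np.linalg.norm(seq.a_body, axis=1), atol=1e-9)
        assert np.allclose(np.linalg.norm(seq.w_global, axis=1),
                           np.linalg.norm(seq.w_body, axis=1), atol=1e-9)

    def test_quaternion_norms(self, rng):
        seq = transform_sequence(rng.normal(size=(100, 3)),
                                 rng.normal(size=(100, 3)) * 40)
        assert np.abs(np.linalg.norm(seq.quaternions, axis=1) - 1).max() <= 1e-9

    def test_nan_rejected_with_index(self):
        ab = np.tile([0.0, 0.0, 1.0], (50, 1))
        ab[17, 1] = np.nan
        with pytest.raises(ValueError, match="17"):
            transform_sequence(ab, np.zeros((50, 3)))

    def test_roll_pitch_wearing_invariance_on_paired_fall(self):
        # the same fall rendered under wearing offsets differing in roll and
        # pitch only: after warm-up, the vertical global acceleration traces
        # coincide (the core purpose of the gravity-aligned transform)
        from fallsense.synthdata import SynthConfig, generate_paired_fall
        cfg = SynthConfig(pre_fall_activity_s=(14.0, 14.0),
                          noise_accel_g=0.0, noise_gyro_dps=0.0, seed=3)
        rng = np.random.default_rng(5)
        ta, tb = generate_paired_fall("forward", cfg, rng,
                                      (0.0, 0.0, 10.0), (20.0, 15.0, 10.0))
        seqs = [transform_sequence(t.accel, t.gyro) for t in (ta, tb)]
        onset = ta.onset_frame
        za, zb = (s.a_global[onset:ta.impact_frame, 2] for s in seqs)
        assert np.abs(za - zb).max() < 0.1


class TestDetectConvergence:
    def test_already_aligned_converges_at_hold(self):
        ab = np.tile([0.0, 0.0, 1.0], (300, 1))
        seq = transform_sequence(ab, np.zeros((300, 3)))
        assert detect_convergence(seq) == pytest.approx(0.5)

    @pytest.mark.parametrize("tilt_deg", [45.0, 90.0])
    def test_tilted_static_converges_within_15s(self, tilt_deg):
        tilt = np.radians(tilt_deg)
        a = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        seq = transform_sequence(np.tile(a, (2000, 1)), np.zeros((2000, 3)))
        t = detect_convergence(seq)
        assert t is not None and t <= 15.0

    def test_perpetual_rotation_never_converges(self):
        # constant fast rotation about x keeps the estimate chasing
        T = 400
        wb = np.tile([200.0, 0.0, 0.0], (T, 1))
        ab = np.zeros((T, 3))
        ab[:, 1] = 1.0  # misaligned and rotating
        seq = transform_sequence(ab, wb)
        assert detect_convergence(seq, angle_tol_deg=1.0) is None

    def test_short_sequence_rejected(self):
        seq = transform_sequence(np.tile([0.0, 0.0, 1.0], (10, 1)), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            detect_convergence(seq, hold_s=0.5)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_rotation_isometry_property(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    v = rng.normal(size=3)
    assert np.isclose(np.linalg.norm(quaternion_to_rotation(q) @ v),
                      np.linalg.norm(v))
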