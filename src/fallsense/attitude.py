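"""Madgwick attitude estimation and body-to-global coordinate transformation.

A waist-worn IMU measures specific force (accelerometer, in g) and angular
rate (gyroscope, in deg/s) in the *body frame* — the frame rigidly attached
to the sensor housing, which co-rotates with the wearing orientation.  The
Madgwick complementary filter fuses gyroscope integration with a normalized
gradient-descent correction toward the accelerometer's gravity direction,
maintaining a unit quaternion ``q`` that rotates body-frame vectors into a
gravity-aligned *global frame* (Z opposing gravity; heading anchored at
filter initialization, since no magnetometer is used).

Conventions
-----------
* Quaternions are Hamilton, scalar-first ``[q0, q1, q2, q3]``, unit norm.
* At rest the accelerometer reads ``+1 g`` along the body axis anti-parallel
  to gravity, so the global gravity reference is ``[0, 0, 1]``.
* Gyroscope input is stored in deg/s and converted to rad/s per step.
* The accelerometer correction is gated off when ``|a| <= epsilon`` (near
  free fall the gravity direction is unobservable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MadgwickConfig",
    "DualFrameSequence",
    "quaternion_multiply",
    "quaternion_conjugate",
    "quaternion_to_rotation",
    "madgwick_step",
    "transform_sequence",
    "detect_convergence",
]

logger = logging.getLogger(__name__)

_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])
_GRAD_FLOOR = 1e-12


@dataclass(frozen=True)
class MadgwickConfig:
    """Filter gains and timing for the Madgwick update.

    Parameters
    ----------
    beta : float
        Accelerometer-correction gain (dimensionless).  Governs how strongly
        the gravity-direction correction pulls against gyroscope integration;
        0 gives pure gyro integration.
    epsilon : float
        Free-fall gating threshold on the accelerometer magnitude, in g.
        The correction step runs only when ``|a| > epsilon``.
    dt : float
        Sample period in seconds (0.01 for 100 Hz streams).
    """

    beta: float = 0.1
    epsilon: float = 0.1
    dt: float = 0.01
    gravity_ref: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.epsilon <= 0 or self.dt <= 0:
            raise ValueError("epsilon and dt must be > 0")

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


@dataclass
class DualFrameSequence:
    """One trial's streams in both frames plus the quaternion trajectory.

    ``a_*`` are in g, ``w_*`` in deg/s; all arrays are ``T x 3`` except
    ``quaternions`` which is ``T x 4`` (the post-update state at each
    sample).  Rotation is an isometry, so per-sample vector norms agree
    between frames.
    """

    a_body: np.ndarray
    w_body: np.ndarray
    a_global: np.ndarray
    w_global: np.ndarray
    quaternions: np.ndarray
    fs: float = 100.0

    def __len__(self) -> int:
        return self.a_body.shape[0]


def quaternion_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p ⊗ q`` of scalar-first quaternions."""
    p0, p1, p2, p3 = p
    q0, q1, q2, q3 = q
    return np.array(
        [
            p0 * q0 - p1 * q1 - p2 * q2 - p3 * q3,
            p0 * q1 + p1 * q0 + p2 * q3 - p3 * q2,
            p0 * q2 - p1 * q3 + p2 * q0 + p3 * q1,
            p0 * q3 + p1 * q2 - p2 * q1 + p3 * q0,
        ]
    )


def quaternion_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping body-frame vectors to the global frame.

    Raises if ``q`` deviates from unit norm by more than 1e-6.  The third
    row of the returned matrix, transposed, is the predicted body-frame
    gravity direction used by the filter's objective function.
    """
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise ValueError("quaternion must be unit norm")
    q0, q1, q2, q3 = q
    return np.array(
        [
            [1 - 2 * (q2 * q2 + q3 * q3), 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), 1 - 2 * (q1 * q1 + q3 * q3), 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), 1 - 2 * (q1 * q1 + q2 * q2)],
        ]
    )


def _gyro_rate(q: np.ndarray, w_dps: np.ndarray) -> np.ndarray:
    """Quaternion rate induced by the body-frame angular velocity (deg/s)."""
    wr = np.deg2rad(np.asarray(w_dps, dtype=float))
    return 0.5 * quaternion_multiply(q, np.array([0.0, wr[0], wr[1], wr[2]]))


def madgwick_step(
    q: np.ndarray, a: np.ndarray, w: np.ndarray, cfg: MadgwickConfig
) -> np.ndarray:
    """One fused filter update; returns the normalized next quaternion.

    The gradient correction runs only when ``|a| > epsilon`` and the
    gradient norm is above a small floor (a vanishing gradient means the
    predicted and measured gravity directions already agree).
    """
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    q_dot = _gyro_rate(q, w)

    a_norm = float(np.linalg.norm(a))
    if a_norm > cfg.epsilon:
        a_hat = a / a_norm
        q0, q1, q2, q3 = q
        f = np.array(
            [
                2.0 * (q1 * q3 - q0 * q2) - a_hat[0],
                2.0 * (q0 * q1 + q2 * q3) - a_hat[1],
                2.0 * (0.5 - q1 * q1 - q2 * q2) - a_hat[2],
            ]
        )
        J = np.array(
            [
                [-2 * q2, 2 * q3, -2 * q0, 2 * q1],
                [2 * q1, 2 * q0, 2 * q3, 2 * q2],
                [0.0, -4 * q1, -4 * q2, 0.0],
            ]
        )
        grad = J.T @ f
        gnorm = float(np.linalg.norm(grad))
        if gnorm > _GRAD_FLOOR:
            q_dot = q_dot - cfg.beta * grad / gnorm
        elif np.any(f != 0.0):
            logger.debug("madgwick_step: zero gradient with |a|>eps; gyro-only update")

    q_next = q + q_dot * cfg.dt
    return q_next / np.linalg.norm(q_next)


def transform_sequence(
    a_body: np.ndarray,
    w_body: np.ndarray,
    cfg: MadgwickConfig | None = None,
    q0: np.ndarray | None = None,
) -> DualFrameSequence:
    """Run the filter over a trial and rotate both streams into the global frame.

    The quaternion state starts at identity (or ``q0``) and is threaded
    sample by sample; each sample is rotated by the matrix of the freshly
    updated quaternion, so the first samples of an arbitrarily-oriented
    trial are only approximately aligned until the filter converges.

    Raises ``ValueError`` on NaN/Inf input, naming the first bad sample.
    """
    cfg = cfg or MadgwickConfig()
    a_body = np.asarray(a_body, dtype=float)
    w_body = np.asarray(w_body, dtype=float)
    if a_body.shape != w_body.shape or a_body.ndim != 2 or a_body.shape[1] != 3:
        raise ValueError("a_body and w_body must be equal-length T x 3 arrays")
    bad = ~np.isfinite(a_body).all(axis=1) | ~np.isfinite(w_body).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite sample at index {int(np.argmax(bad))}")

    T = a_body.shape[0]
    q = _IDENTITY.copy() if q0 is None else np.asarray(q0, dtype=float).copy()
    quats = np.empty((T, 4))
    a_glob = np.empty_like(a_body)
    w_glob = np.empty_like(w_body)
    for t in range(T):
        q = madgwick_step(q, a_body[t], w_body[t], cfg)
        R = quaternion_to_rotation(q)
        a_glob[t] = R @ a_body[t]
        w_glob[t] = R @ w_body[t]
        quats[t] = q
    return DualFrameSequence(a_body, w_body, a_glob, w_glob, quats, fs=cfg.fs)


def detect_convergence(
    seq: DualFrameSequence, angle_tol_deg: float = 5.0, hold_s: float = 0.5
) -> float | None:
    """Earliest time (s) at which global acceleration stays within
    ``angle_tol_deg`` of vertical for ``hold_s`` consecutive seconds.

    Intended for static or quasi-static streams (warm-up measurement).
    Returns ``None`` if the criterion never holds; raises if the sequence
    is shorter than the hold window.
    """
    hold_n = int(round(hold_s * seq.fs))
    if len(seq) < hold_n:
        raise ValueError("sequence shorter than the hold window")
    a = seq.a_global
    norms = np.linalg.norm(a, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norms > 0, a[:, 2] / np.where(norms > 0, norms, 1.0), -1.0)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = angles < angle_tol_deg
    runs = np.convolve(ok.astype(int), np.ones(hold_n, dtype=int), mode="valid")
    hits = np.nonzero(runs == hold_n)[0]
    if hits.size == 0:
        return None
    return float(hits[0] + hold_n) / seq.fs
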