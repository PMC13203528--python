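"""Deterministic generator of annotated synthetic IMU trials.

Emulates waist-worn 100 Hz recordings in the structure the pipeline expects:
ADL trials lasting tens of seconds with no impact, and fall trials with an
annotated fall onset and impact frame, a sub-second descent during which the
trunk rotates toward horizontal and the specific-force magnitude dips toward
free fall, and a high-magnitude spike *after* the impact frame (so that
pre-impact truncation removes it and a classifier must rely on pre-impact
dynamics alone).

Physical model
--------------
Each trial is a trunk orientation trajectory (roll/pitch/yaw over time)
plus a linear acceleration of the centre of mass in the global frame.  A
per-subject constant *wearing offset* rotation (the sensor mounted ajar on
the waist) composes with the trunk motion; the accelerometer then reads

    a_body(t) = R(t)^T (g + a_lin(t)) + noise,   g = [0, 0, 1] g,

with ``R(t)`` the sensor-to-global rotation, and the gyroscope reads the
body-frame angular velocity consistent with the orientation derivative
(so pure quaternion integration of the generated gyro stream recovers the
generating trajectory up to first-order Euler error — the ground-truth
oracle for the attitude estimator).  Every generated trial carries its
ground truth in ``ImuTrial.truth``.

All randomness flows from the config seed through per-trial counter-derived
substreams, so datasets are bit-reproducible and independent of generation
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .preprocess import ImuTrial

__all__ = [
    "SynthConfig",
    "generate_adl_trial",
    "generate_fall_trial",
    "generate_paired_fall",
    "generate_dataset",
    "ADL_KINDS",
    "FALL_DIRECTIONS",
]

ADL_KINDS = ("walk", "static", "sit_stand", "jump")
FALL_DIRECTIONS = ("forward", "backward", "lateral")

_ADL_CODES = {"static": "D01", "walk": "D02", "sit_stand": "D03", "jump": "D04",
              "sit_ground": "D05"}
_FALL_CODES = {"forward": "F01", "backward": "F02", "lateral": "F03"}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 8 subjects with 4 ADL and 3 fall trials each; ADLs last
    10-30 s; falls descend over 300-600 ms after 2-4 s of ordinary
    activity; wearing offsets are drawn once per subject, uniformly within
    +/-35 degrees per axis; sensor noise is MEMS-grade (0.02 g, 1 deg/s).
    """

    n_subjects: int = 8
    trials_per_subject: tuple[int, int] = (4, 3)  # (n_adl, n_fall)
    fs: float = 100.0
    adl_duration_s: tuple[float, float] = (10.0, 30.0)
    fall_descent_ms: tuple[float, float] = (300.0, 600.0)
    pre_fall_activity_s: tuple[float, float] = (2.0, 4.0)
    wearing_offset_deg: tuple[float, float, float] = (35.0, 35.0, 35.0)
    walk_gait_hz: tuple[float, float] = (1.6, 2.4)
    adl_kinds: tuple[str, ...] = ADL_KINDS
    noise_accel_g: float = 0.02
    noise_gyro_dps: float = 1.0
    seed: int = 0

    @classmethod
    def orientation_stress(cls, seed: int = 0, **kw) -> "SynthConfig":
        """Large inter-subject wearing offsets (+/-75 deg per axis), the
        regime where body-frame waveforms of identical motions diverge most.

        Pre-fall activity is lengthened so the attitude filter converges
        from such offsets before the fall begins (deployment prescribes a
        warm-up for the same reason); without it the global-frame streams
        during falls are dominated by unconverged attitude error and carry
        no orientation-invariant information.  The ADL mix leads with the
        sit-to-ground hard negative, whose rotation and dip magnitudes
        overlap a fall's pre-impact phase: only the motion's direction
        relative to gravity separates the classes, which is the regime the
        coordinate transformation exists for.
        """
        kw.setdefault("pre_fall_activity_s", (12.0, 16.0))
        kw.setdefault("adl_kinds", ("sit_ground", "walk", "jump"))
        return cls(wearing_offset_deg=(75.0, 75.0, 75.0), seed=seed, **kw)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


# ---------------------------------------------------------------------------
# orientation/kinematics helpers


def _rot_from_euler_deg(euler_deg: np.ndarray) -> Rotation:
    """Yaw-pitch-roll (intrinsic ZYX) rotation(s) from degrees, columns
    (roll, pitch, yaw)."""
    e = np.atleast_2d(euler_deg)
    return Rotation.from_euler("ZYX", np.column_stack([e[:, 2], e[:, 1], e[:, 0]]),
                               degrees=True)


def _gyro_from_rotations(rots: Rotation, dt: float) -> np.ndarray:
    """Body-frame angular velocity (deg/s) whose exact integration steps
    through the given orientation sequence."""
    n = len(rots)
    w = np.zeros((n, 3))
    if n > 1:
        rel = rots[:-1].inv() * rots[1:]
        w[:-1] = np.degrees(rel.as_rotvec()) / dt
        w[-1] = w[-2]
    return w


def _render(
    euler_trunk_deg: np.ndarray,
    a_lin_global: np.ndarray,
    mount_euler_deg: tuple[float, float, float],
    cfg: SynthConfig,
    noise_rng: np.random.Generator,
    impact_spike: tuple[int, int, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Render sensor-frame samples (T x 6) from a trunk trajectory."""
    r_trunk = _rot_from_euler_deg(euler_trunk_deg)
    r_mount = _rot_from_euler_deg(np.asarray(mount_euler_deg, dtype=float))
    r_sensor = r_trunk * r_mount

    g_plus = a_lin_global + np.array([0.0, 0.0, 1.0])
    a_body = r_sensor.inv().apply(g_plus)
    if impact_spike is not None:
        start, length, mag = impact_spike
        a_body[start:start + length] += mag * noise_rng.standard_normal((min(length, len(a_body) - start), 3)) * 0.2
        a_body[start:start + length, 2] += mag
    w_body = _gyro_from_rotations(r_sensor, cfg.dt)

    T = a_body.shape[0]
    if cfg.noise_accel_g:
        a_body = a_body + noise_rng.normal(0.0, cfg.noise_accel_g, (T, 3))
    if cfg.noise_gyro_dps:
        w_body = w_body + noise_rng.normal(0.0, cfg.noise_gyro_dps, (T, 3))

    quats_xyzw = r_sensor.as_quat()
    quats = np.column_stack([quats_xyzw[:, 3], quats_xyzw[:, :3]])  # scalar-first
    truth = {
        "quaternions": quats,
        "euler_trunk_deg": euler_trunk_deg,
        "mount_euler_deg": np.asarray(mount_euler_deg, dtype=float),
        "a_lin_global": a_lin_global,
    }
    return np.column_stack([a_body, w_body]), truth


def _smooth_bump(n: int) -> np.ndarray:
    """0 -> 1 -> 0 over n samples with zero-slope ends."""
    return np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2


def _adl_motion(kind: str, n: int, cfg: SynthConfig, rng: np.random.Generator):
    """Trunk euler angles (deg) and global linear acceleration (g) for one ADL."""
    t = np.arange(n) * cfg.dt
    euler = np.zeros((n, 3))  # roll, pitch, yaw
    a_lin = np.zeros((n, 3))
    if kind == "static":
        pass
    elif kind == "walk":
        f = rng.uniform(*cfg.walk_gait_hz)
        amp = rng.uniform(0.10, 0.22)
        phase = rng.uniform(0, 2 * np.pi)
        a_lin[:, 2] = amp * np.sin(2 * np.pi * f * t + phase)
        a_lin[:, 0] = 0.4 * amp * np.sin(4 * np.pi * f * t + phase)
        euler[:, 1] = 3.0 * np.sin(2 * np.pi * f * t + phase)
        euler[:, 0] = 2.0 * np.sin(2 * np.pi * f * t + phase + np.pi / 2)
        euler[:, 2] = 8.0 * np.sin(2 * np.pi * 0.1 * t)
    elif kind == "sit_stand":
        cycle = rng.uniform(2.5, 4.0)
        tilt = rng.uniform(18.0, 30.0)
        euler[:, 1] = tilt * np.sin(np.pi * (t % cycle) / cycle) ** 2
        a_lin[:, 2] = 0.12 * np.sin(2 * np.pi * (t % cycle) / cycle)
    elif kind == "sit_ground":
        # rapid sit-down onto the floor: abrupt trunk tilt with a partial
        # free-fall dip, then recovery — the rotational hard negative whose
        # magnitudes overlap a fall's pre-impact phase; only the direction
        # of motion relative to gravity separates the two
        start = int(rng.uniform(1.0, max(n * cfg.dt - 4.0, 1.5)) * cfg.fs)
        drop_n = int(rng.uniform(0.45, 0.70) * cfg.fs)
        hold_n = int(rng.uniform(0.8, 1.5) * cfg.fs)
        rec_n = int(1.2 * cfg.fs)
        tilt = rng.uniform(30.0, 52.0)  # peak rates overlap a fall's
        dip = rng.uniform(0.30, 0.42)   # pre-cutoff descent signature
        end_drop = min(start + drop_n, n)
        tau = np.arange(end_drop - start) / max(drop_n - 1, 1)
        euler[start:end_drop, 1] = -tilt * (1 - np.cos(np.pi * tau)) / 2.0
        a_lin[start:end_drop, 2] = -dip * tau**2
        hold_sl = slice(end_drop, min(end_drop + hold_n, n))
        euler[hold_sl, 1] = -tilt
        rec_start = hold_sl.stop
        rec_end = min(rec_start + rec_n, n)
        tau_r = np.arange(rec_end - rec_start) / max(rec_n - 1, 1)
        euler[rec_start:rec_end, 1] = -tilt * (1 + np.cos(np.pi * tau_r)) / 2.0
        a_lin[rec_start:rec_end, 2] = 0.10 * np.sin(np.pi * tau_r)
    elif kind == "jump":
        n_jumps = max(1, int(n * cfg.dt / 6.0))
        for _ in range(n_jumps):
            start = rng.integers(50, max(n - 80, 51))
            crouch, flight, land = 12, rng.integers(15, 25), 6
            a_lin[start:start + crouch, 2] += 0.35 * _smooth_bump(crouch)
            fl = slice(start + crouch, start + crouch + flight)
            a_lin[fl, 2] -= 0.8
            ld = slice(start + crouch + flight, start + crouch + flight + land)
            a_lin[ld, 2] += 1.2 * _smooth_bump(land)
    else:
        raise ValueError(f"unknown ADL kind {kind!r}")
    return euler, a_lin


def _fall_motion(direction: str, cfg: SynthConfig, rng: np.random.Generator):
    """Pre-fall activity + descent + post-impact lying; returns the
    trajectory, linear acceleration, onset/impact frames and spike window."""
    if direction not in FALL_DIRECTIONS:
        raise ValueError(f"unknown fall direction {direction!r}")
    pre_s = rng.uniform(*cfg.pre_fall_activity_s)
    pre_n = int(round(pre_s * cfg.fs))
    pre_kind = "walk" if rng.random() < 0.5 else "static"
    euler_pre, a_pre = _adl_motion(pre_kind, pre_n, cfg, rng)
    # ease the pre-fall oscillation out so the descent starts from quiet
    fade = np.clip((pre_n - np.arange(pre_n)) / (0.5 * cfg.fs), 0, 1)[:, None]
    euler_pre, a_pre = euler_pre * fade, a_pre * fade

    desc_ms = rng.uniform(*cfg.fall_descent_ms)
    desc_n = max(int(round(desc_ms / 1000.0 * cfg.fs)), 8)
    tau = np.arange(desc_n) / (desc_n - 1)
    tilt_max = rng.uniform(60.0, 85.0)
    tilt = tilt_max * (1 - np.cos(np.pi * tau)) / 2.0
    euler_desc = np.zeros((desc_n, 3))
    axis, sign = {"forward": (1, 1.0), "backward": (1, -1.0), "lateral": (0, 1.0)}[direction]
    euler_desc[:, axis] = sign * tilt
    dip_max = rng.uniform(0.55, 0.80)
    a_desc = np.zeros((desc_n, 3))
    a_desc[:, 2] = -dip_max * tau**1.2
    a_desc[:, 0 if axis == 1 else 1] = sign * 0.25 * tau

    post_n = int(round(0.5 * cfg.fs))
    euler_post = np.tile(euler_desc[-1], (post_n, 1))
    a_post = np.zeros((post_n, 3))

    euler = np.vstack([euler_pre, euler_desc, euler_post])
    a_lin = np.vstack([a_pre, a_desc, a_post])
    onset, impact = pre_n, pre_n + desc_n
    spike = (impact, 5, rng.uniform(2.5, 4.5))
    return euler, a_lin, onset, impact, spike


# ---------------------------------------------------------------------------
# public generators


def generate_adl_trial(
    kind: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    subject_id: str = "S01",
    mount_euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    trial_id: str = "",
) -> ImuTrial:
    """One ADL trial of the given kind (no impact annotation)."""
    dur = rng.uniform(*cfg.adl_duration_s)
    n = int(round(dur * cfg.fs))
    euler, a_lin = _adl_motion(kind, n, cfg, rng)
    samples, truth = _render(euler, a_lin, mount_euler_deg, cfg, rng)
    return ImuTrial(subject_id, _ADL_CODES[kind], False, samples, cfg.fs,
                    trial_id=trial_id or f"{subject_id}-{kind}", truth=truth)


def generate_fall_trial(
    direction: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    subject_id: str = "S01",
    mount_euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    trial_id: str = "",
) -> ImuTrial:
    """One fall trial: pre-fall activity, annotated descent with a partial
    free-fall dip, impact frame, and a post-impact spike."""
    euler, a_lin, onset, impact, spike = _fall_motion(direction, cfg, rng)
    samples, truth = _render(euler, a_lin, mount_euler_deg, cfg, rng,
                             impact_spike=spike)
    return ImuTrial(subject_id, _FALL_CODES[direction], True, samples, cfg.fs,
                    onset_frame=onset, impact_frame=impact,
                    trial_id=trial_id or f"{subject_id}-{direction}", truth=truth)


def generate_paired_fall(
    direction: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    mount_a_deg: tuple[float, float, float],
    mount_b_deg: tuple[float, float, float],
    subject_id: str = "S01",
) -> tuple[ImuTrial, ImuTrial]:
    """The same underlying fall motion rendered under two wearing offsets,
    for orientation-invariance checks.  Sensor noise is drawn independently
    per rendering."""
    euler, a_lin, onset, impact, spike = _fall_motion(direction, cfg, rng)
    noise_a = np.random.default_rng(rng.integers(2**31))
    noise_b = np.random.default_rng(rng.integers(2**31))
    sa, ta = _render(euler, a_lin, mount_a_deg, cfg, noise_a, impact_spike=spike)
    sb, tb = _render(euler, a_lin, mount_b_deg, cfg, noise_b, impact_spike=spike)
    make = lambda s, tr, tag: ImuTrial(subject_id, _FALL_CODES[direction], True, s,
                                       cfg.fs, onset_frame=onset, impact_frame=impact,
                                       trial_id=f"{subject_id}-{direction}-{tag}", truth=tr)
    return make(sa, ta, "a"), make(sb, tb, "b")


def generate_dataset(cfg: SynthConfig) -> tuple[list[ImuTrial], pd.DataFrame]:
    """Full synthetic cohort plus a manifest of annotations.

    Each subject gets one constant wearing offset applied to all of their
    trials, ``n_adl`` ADL trials cycling through the activity kinds, and
    ``n_fall`` fall trials cycling through the fall directions.  Every trial
    draws from a substream keyed by (seed, subject index, trial index).
    """
    n_adl, n_fall = cfg.trials_per_subject
    trials: list[ImuTrial] = []
    rows = []
    for si in range(cfg.n_subjects):
        sid = f"S{si + 1:02d}"
        srng = np.random.default_rng(np.random.SeedSequence([cfg.seed, si]))
        mount = tuple(srng.uniform(-m, m) for m in cfg.wearing_offset_deg)
        for tj in range(n_adl + n_fall):
            trng = np.random.default_rng(np.random.SeedSequence([cfg.seed, si, tj]))
            tid = f"{sid}T{tj + 1:02d}"
            if tj < n_adl:
                kind = cfg.adl_kinds[tj % len(cfg.adl_kinds)]
                trial = generate_adl_trial(kind, cfg, trng, sid, mount, tid)
            else:
                direction = FALL_DIRECTIONS[(tj - n_adl) % len(FALL_DIRECTIONS)]
                trial = generate_fall_trial(direction, cfg, trng, sid, mount, tid)
            trials.append(trial)
            rows.append({
                "trial_id": tid, "subject_id": sid,
                "activity_code": trial.activity_code, "is_fall": trial.is_fall,
                "n_samples": len(trial),
                "onset_frame": trial.onset_frame, "impact_frame": trial.impact_frame,
            })
    return trials, pd.DataFrame(rows)
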