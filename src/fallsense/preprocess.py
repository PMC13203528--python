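"""Trial truncation, low-pass filtering, sliding-window extraction, labeling.

Offline dataset construction for pre-impact fall detection runs, per trial:

1. **Truncate** fall trials at ``t_cut = impact_frame - margin`` (250 ms
   before impact), so the classifier only ever sees pre-impact motion and a
   protection device retains deployment time.
2. **Filter** all six channels with a causal 4th-order Butterworth low-pass
   (8 Hz cutoff) — single-pass IIR, for parity with streaming deployment.
3. **Transform** the whole filtered trial with the Madgwick filter into the
   gravity-aligned global frame (state continuous across windows).
4. **Window**: fall trials use *reverse* sliding windows anchored so the
   first window ends exactly at the cutoff (the most discriminative region);
   ADL trials use conventional forward windows.  875 ms windows at 100 Hz
   with 60% overlap give 87 samples per window and a 34-sample stride.

Index convention is 0-based, half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import signal

from .attitude import MadgwickConfig, transform_sequence

__all__ = [
    "ImuTrial",
    "WindowingConfig",
    "WindowDataset",
    "TrialTooShortError",
    "butterworth_lowpass",
    "truncate_pre_impact",
    "reverse_windows",
    "forward_windows",
    "label_window",
    "build_dataset",
]

logger = logging.getLogger(__name__)

GRAVITY_MS2 = 9.80665


class TrialTooShortError(ValueError):
    """Raised when a truncated fall trial cannot fill a single window."""


@dataclass
class ImuTrial:
    """One recording: a ``T x 6`` stream (ax,ay,az in g; wx,wy,wz in deg/s)
    at ``fs`` Hz with per-trial annotations.

    For fall trials ``onset_frame`` marks the start of the fall phase and
    ``impact_frame`` the ground impact; both index into ``samples``.  After
    pre-impact truncation ``impact_frame`` is ``None`` and the fall phase
    extends to the trial end.
    """

    subject_id: str
    activity_code: str
    is_fall: bool
    samples: np.ndarray
    fs: float = 100.0
    onset_frame: int | None = None
    impact_frame: int | None = None
    trial_id: str = ""
    truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ValueError("samples must be a T x 6 array")
        if self.is_fall and self.impact_frame is not None:
            if self.onset_frame is None or not (
                self.onset_frame < self.impact_frame <= len(self.samples)
            ):
                raise ValueError("fall trial requires onset_frame < impact_frame <= T")

    @property
    def accel(self) -> np.ndarray:
        return self.samples[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.samples[:, 3:]

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class WindowingConfig:
    """Window geometry.  Derived sizes follow the floor formulas
    ``n_win = floor(window_ms * fs / 1000)`` and
    ``step = floor(n_win * (1 - overlap))``."""

    window_ms: float = 875.0
    overlap: float = 0.6
    margin_ms: float = 250.0
    fs: float = 100.0
    overlap_threshold: float = 0.5

    @property
    def n_win(self) -> int:
        return int(np.floor(self.window_ms * self.fs / 1000.0))

    @property
    def step(self) -> int:
        return int(np.floor(self.n_win * (1.0 - self.overlap)))

    @property
    def margin_samples(self) -> int:
        return int(np.floor(self.margin_ms * self.fs / 1000.0))


@dataclass
class WindowDataset:
    """Stacked dual-frame windows: ``X`` is ``(n, 4, 3, n_win)`` float32 with
    stream order (body accel, body gyro, global accel, global gyro)."""

    X: np.ndarray
    y: np.ndarray
    trial_ids: np.ndarray
    subject_ids: np.ndarray
    activity_codes: np.ndarray
    end_indices: np.ndarray
    split: str | None = None

    STREAMS = ("body_accel", "body_gyro", "global_accel", "global_gyro")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray, split: str | None = None) -> "WindowDataset":
        return WindowDataset(
            self.X[mask],
            self.y[mask],
            self.trial_ids[mask],
            self.subject_ids[mask],
            self.activity_codes[mask],
            self.end_indices[mask],
            split if split is not None else self.split,
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            X=self.X,
            y=self.y,
            trial_ids=self.trial_ids,
            subject_ids=self.subject_ids,
            activity_codes=self.activity_codes,
            end_indices=self.end_indices,
            split=np.array(self.split or ""),
        )

    @classmethod
    def load(cls, path) -> "WindowDataset":
        with np.load(path, allow_pickle=False) as z:
            split = str(z["split"]) or None
            return cls(
                z["X"], z["y"], z["trial_ids"], z["subject_ids"],
                z["activity_codes"], z["end_indices"], split,
            )


def butterworth_lowpass(
    samples: np.ndarray, fs: float, order: int = 4, fc: float = 8.0
) -> np.ndarray:
    """Causal per-channel Butterworth low-pass (single-pass IIR, unit DC gain).

    Zero-phase forward-backward filtering is deliberately not used: the
    deployed firmware filters each newly sampled point sequentially, and the
    offline pipeline mirrors that causality.
    """
    if fc >= fs / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfilt(sos, np.asarray(samples, dtype=float), axis=0)


def truncate_pre_impact(trial: ImuTrial, cfg: WindowingConfig) -> ImuTrial:
    """Remove all samples at/after ``impact_frame - margin``.

    ADL trials (no impact annotation) are returned unchanged.  Raises
    :class:`TrialTooShortError` when the truncated length cannot fill a
    window; :func:`build_dataset` logs and excludes such trials.
    """
    if not trial.is_fall or trial.impact_frame is None:
        return trial
    t_cut = trial.impact_frame - cfg.margin_samples
    if t_cut < cfg.n_win:
        raise TrialTooShortError(
            f"trial {trial.trial_id or trial.activity_code}: truncated length "
            f"{max(t_cut, 0)} < window length {cfg.n_win}"
        )
    return replace(
        trial,
        samples=trial.samples[:t_cut].copy(),
        impact_frame=None,
        onset_frame=trial.onset_frame,
    )


def reverse_windows(n_samples: int, cfg: WindowingConfig) -> list[tuple[int, int]]:
    """Window index ranges anchored at the sequence end, sliding backward.

    The first emitted window ends exactly at ``n_samples``; subsequent ends
    step back by ``cfg.step`` until a full window no longer fits.
    """
    out: list[tuple[int, int]] = []
    pos = n_samples
    while pos - cfg.n_win >= 0:
        out.append((pos - cfg.n_win, pos))
        pos -= cfg.step
    return out


def forward_windows(n_samples: int, cfg: WindowingConfig) -> list[tuple[int, int]]:
    """Conventional forward windows from index 0; a trailing segment shorter
    than one window is discarded."""
    out: list[tuple[int, int]] = []
    start = 0
    while start + cfg.n_win <= n_samples:
        out.append((start, start + cfg.n_win))
        start += cfg.step
    return out


def label_window(
    window: tuple[int, int], trial: ImuTrial, overlap_threshold: float = 0.5
) -> int:
    """Label 1 iff the window's overlap with the annotated fall phase reaches
    ``overlap_threshold``; windows of ADL trials are always 0.

    The fall phase runs from ``onset_frame`` to the cutoff (the trial end
    after truncation, else ``impact_frame``).  Because pre-impact truncation
    leaves fall phases shorter than one window, the overlap ratio is
    normalized by ``min(window length, fall-phase length)``: the window
    anchored at the cutoff, which contains the entire surviving fall phase,
    scores 1.  The threshold comparison is inclusive.
    """
    if not trial.is_fall or trial.onset_frame is None:
        return 0
    start, end = window
    phase_end = trial.impact_frame if trial.impact_frame is not None else len(trial)
    phase_len = phase_end - trial.onset_frame
    if phase_len <= 0:
        return 0
    inter = max(0, min(end, phase_end) - max(start, trial.onset_frame))
    ratio = inter / min(end - start, phase_len)
    return int(ratio >= overlap_threshold)


def build_dataset(
    trials: Iterable[ImuTrial],
    cfg: WindowingConfig | None = None,
    madgwick_cfg: MadgwickConfig | None = None,
    split: str | None = None,
) -> WindowDataset:
    """Run the full per-trial pipeline (truncate → filter → Madgwick →
    window) and stack the four-stream windows.

    Fall trials too short to survive truncation are excluded with a logged
    reason.  The Madgwick filter runs once over each whole truncated trial,
    so quaternion state is continuous across that trial's windows.
    """
    cfg = cfg or WindowingConfig()
    madgwick_cfg = madgwick_cfg or MadgwickConfig(dt=1.0 / cfg.fs)
    xs, ys, tids, sids, acts, ends = [], [], [], [], [], []
    for trial in trials:
        try:
            trial = truncate_pre_impact(trial, cfg)
        except TrialTooShortError as exc:
            logger.warning("excluding trial: %s", exc)
            continue
        filtered = butterworth_lowpass(trial.samples, trial.fs)
        seq = transform_sequence(filtered[:, :3], filtered[:, 3:], madgwick_cfg)
        ranges = (
            reverse_windows(len(trial), cfg)
            if trial.is_fall
            else forward_windows(len(trial), cfg)
        )
        for start, end in ranges:
            win = np.stack(
                [
                    seq.a_body[start:end].T,
                    seq.w_body[start:end].T,
                    seq.a_global[start:end].T,
                    seq.w_global[start:end].T,
                ]
            )
            xs.append(win.astype(np.float32))
            ys.append(label_window((start, end), trial, cfg.overlap_threshold))
            tids.append(trial.trial_id or f"{trial.subject_id}:{trial.activity_code}")
            sids.append(trial.subject_id)
            acts.append(trial.activity_code)
            ends.append(end)
    n_win = cfg.n_win
    if xs:
        X = np.stack(xs)
    else:
        X = np.empty((0, 4, 3, n_win), dtype=np.float32)
    return WindowDataset(
        X,
        np.asarray(ys, dtype=np.int64),
        np.asarray(tids, dtype=object).astype(str),
        np.asarray(sids, dtype=object).astype(str),
        np.asarray(acts, dtype=object).astype(str),
        np.asarray(ends, dtype=np.int64),
        split,
    )
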