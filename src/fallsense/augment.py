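"""Training-set-only augmentation of fall windows.

Windowed fall samples are far scarcer than ADL samples (the fall phase lasts
under a second while ADLs run tens of seconds), so each fall window in the
training split is expanded with jittered / scaled / time-warped variants:

* **jitter** — additive Gaussian sensor noise, sigma in signal units;
* **scaling** — one Gaussian scalar factor per window, emulating body-size
  differences in movement amplitude;
* **time warping** — a smooth monotone remapping of the time axis built from
  a cubic spline over random knot magnitudes, emulating individual
  differences in fall speed.

Each augmented copy applies all three transforms in sequence
(jitter → scale → warp) with independent draws.  The warp and scale are
shared across all four streams of a window so body/global timing stays
consistent; jitter is drawn independently per stream and channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import WindowDataset

__all__ = ["AugmentConfig", "jitter", "scale", "time_warp", "augment_falls"]

logger = logging.getLogger(__name__)

_MIN_WARP_SPEED = 0.05


@dataclass(frozen=True)
class AugmentConfig:
    jitter_sigma: float = 0.04
    scale_mean: float = 1.0
    scale_sd: float = 0.10
    warp_sigma: float = 0.15
    warp_knots: int = 4
    n_copies: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        if self.warp_knots < 2:
            raise ValueError("warp_knots must be >= 2")


def jitter(window: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Elementwise additive Gaussian noise; shape preserved."""
    window = np.asarray(window)
    if sigma == 0:
        return window.copy()
    return window + rng.normal(0.0, sigma, size=window.shape)


def scale(
    window: np.ndarray, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply the whole window by one Gaussian scalar factor."""
    factor = float(rng.normal(mean, sd)) if sd != 0 else mean
    return np.asarray(window) * factor


def _warp_time_axis(
    n: int, sigma: float, knots: int, rng: np.random.Generator
) -> np.ndarray:
    """Monotone remapped time axis of length ``n`` with fixed endpoints.

    A cubic spline through ``knots + 2`` evenly spaced knot magnitudes drawn
    from N(1, sigma^2) (endpoints included) defines a local time-advance
    speed; its cumulative integral, rescaled to end at ``n - 1``, is the new
    time axis.  Speeds are floored at a small positive value so the
    cumulative warp is always monotone (a heavy clip is logged).
    """
    xk = np.linspace(0, n - 1, knots + 2)
    yk = rng.normal(1.0, sigma, size=knots + 2) if sigma != 0 else np.ones(knots + 2)
    speeds = CubicSpline(xk, yk)(np.arange(n))
    if np.any(speeds < _MIN_WARP_SPEED):
        logger.debug("time_warp: clipping %d non-positive speeds", int((speeds < _MIN_WARP_SPEED).sum()))
        speeds = np.clip(speeds, _MIN_WARP_SPEED, None)
    cum = np.concatenate([[0.0], np.cumsum((speeds[:-1] + speeds[1:]) / 2.0)])
    return cum * (n - 1) / cum[-1]


def time_warp(
    window: np.ndarray, sigma: float, knots: int, rng: np.random.Generator
) -> np.ndarray:
    """Apply one smooth monotone time warp to every channel of a window.

    Accepts ``(..., n)`` arrays; the same warp is applied along the last
    axis of every leading slice, and values are linearly re-interpolated
    back onto the original ``n``-sample grid (endpoints exactly preserved).
    """
    window = np.asarray(window, dtype=float)
    n = window.shape[-1]
    if n < knots + 2:
        raise ValueError("window shorter than knots + 2")
    t_new = _warp_time_axis(n, sigma, knots, rng)
    t_old = np.arange(n, dtype=float)
    flat = window.reshape(-1, n)
    out = np.empty_like(flat)
    for i in range(flat.shape[0]):
        out[i] = np.interp(t_new, t_old, flat[i])
    return out.reshape(window.shape)


def augment_falls(dataset: WindowDataset, cfg: AugmentConfig) -> WindowDataset:
    """Expand every fall window with ``cfg.n_copies`` augmented variants.

    The original windows (both classes) are retained; ADL windows are never
    touched.  Refuses to run on a dataset flagged as a test split — the
    leakage guard for the augment-after-split contract.
    """
    if dataset.split == "test":
        raise ValueError("augmentation is restricted to training splits")
    fall_idx = np.nonzero(dataset.y == 1)[0]
    if fall_idx.size == 0 or cfg.n_copies == 0:
        return dataset
    rng = np.random.default_rng(cfg.seed)
    xs, ys, tids, sids, acts, ends = (
        [dataset.X],
        [dataset.y],
        [dataset.trial_ids],
        [dataset.subject_ids],
        [dataset.activity_codes],
        [dataset.end_indices],
    )
    new = []
    for i in fall_idx:
        for _ in range(cfg.n_copies):
            w = jitter(dataset.X[i].astype(float), cfg.jitter_sigma, rng)
            w = scale(w, cfg.scale_mean, cfg.scale_sd, rng)
            w = time_warp(w, cfg.warp_sigma, cfg.warp_knots, rng)
            new.append(w.astype(np.float32))
    reps = cfg.n_copies
    xs.append(np.stack(new))
    ys.append(np.ones(fall_idx.size * reps, dtype=dataset.y.dtype))
    tids.append(np.repeat(dataset.trial_ids[fall_idx], reps))
    sids.append(np.repeat(dataset.subject_ids[fall_idx], reps))
    acts.append(np.repeat(dataset.activity_codes[fall_idx], reps))
    ends.append(np.repeat(dataset.end_indices[fall_idx], reps))
    return WindowDataset(
        np.concatenate(xs),
        np.concatenate(ys),
        np.concatenate(tids),
        np.concatenate(sids),
        np.concatenate(acts),
        np.concatenate(ends),
        dataset.split,
    )
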