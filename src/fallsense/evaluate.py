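"""Window- and trial-level metrics, false-positive analysis, lead time.

Two evaluation granularities are used:

* **window-level** — every window judged independently (auxiliary metric);
* **trial-level max-voting** — a trial's score is the maximum window
  probability; the trial is called a fall when that score is *not lower
  than* 0.5 (inclusive).  This mirrors deployment, where one window above
  threshold triggers the alarm.

Rolling inference replays deployment on a full (untruncated) fall trial:
the filter and attitude estimator run continuously from the recording
start, an 875 ms window advances with a 340 ms stride, ending strictly
before the impact frame, and the alarm time is the end of the first window
whose fall probability *exceeds* 0.5 (strict, per the deployment rule).
The lead time is ``impact time - alarm time``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attitude import MadgwickConfig, transform_sequence
from .preprocess import ImuTrial, WindowingConfig, butterworth_lowpass

__all__ = [
    "LeadTimeResult",
    "window_metrics",
    "trial_max_voting",
    "per_activity_fp",
    "rolling_inference",
    "lead_time_summary",
    "plot_lead_times",
]


@dataclass(frozen=True)
class LeadTimeResult:
    """Rolling-inference outcome for one fall trial.  ``lead`` is in seconds
    (positive: alarm strictly pre-impact) or ``None`` for a miss."""

    trial_id: str
    t_impact: float
    t_alarm: float | None
    lead: float | None
    reason: str | None = None

    @property
    def detected(self) -> bool:
        return self.t_alarm is not None


def _metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict:
    total = tp + tn + fp + fn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
        "accuracy": (tp + tn) / total,
        "recall": rec, "specificity": spe, "precision": prec, "f1": f1,
    }


def window_metrics(probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """Confusion counts and the standard metric set over windows.

    Decisions use ``prob >= threshold``.  F1 is 0 by convention when both
    precision and recall vanish.  Raises on empty input.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.size == 0:
        raise ValueError("empty prediction vector")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must align")
    pred = probs >= threshold
    pos = labels == 1
    return _metrics_from_counts(
        int((pred & pos).sum()), int((~pred & ~pos).sum()),
        int((pred & ~pos).sum()), int((~pred & pos).sum()),
    )


def trial_max_voting(
    window_probs: np.ndarray,
    trial_ids: np.ndarray,
    window_labels: np.ndarray,
    threshold: float = 0.5,
    expected_trials: np.ndarray | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Max-voting trial decisions and metrics.

    The trial score is the max over its windows and the decision threshold
    is inclusive (``score >= threshold``).  The trial's ground truth is 1
    iff any of its windows is labeled 1 (fall trials always contain the
    window anchored at the cutoff).  If ``expected_trials`` is given, any
    expected trial with zero windows raises.
    Returns (metrics, per-trial frame with score/decision/label).
    """
    probs = np.asarray(window_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("no windows to vote over")
    df = pd.DataFrame({
        "trial_id": np.asarray(trial_ids).astype(str),
        "prob": probs,
        "label": np.asarray(window_labels),
    })
    per = df.groupby("trial_id", sort=True).agg(
        score=("prob", "max"), label=("label", "max"))
    if expected_trials is not None:
        missing = set(map(str, expected_trials)) - set(per.index)
        if missing:
            raise ValueError(f"trials with zero windows: {sorted(missing)}")
    per["decision"] = per["score"] >= threshold
    metrics = _metrics_from_counts(
        int((per.decision & (per.label == 1)).sum()),
        int((~per.decision & (per.label == 0)).sum()),
        int((per.decision & (per.label == 0)).sum()),
        int((~per.decision & (per.label == 1)).sum()),
    )
    return metrics, per.reset_index()


def per_activity_fp(decisions: np.ndarray, activity_codes: np.ndarray) -> pd.DataFrame:
    """False-positive table over ADL trials grouped by activity code.

    ``decisions`` are the per-trial fall calls (boolean) for ADL trials
    only.  Returns one row per activity with trial count, FP count and FP
    rate (percent, 2 decimals), plus an overall ``Total`` row.
    """
    df = pd.DataFrame({
        "activity": np.asarray(activity_codes).astype(str),
        "fp": np.asarray(decisions, dtype=bool),
    })
    grouped = df.groupby("activity", sort=True).agg(
        trials=("fp", "size"), FP=("fp", "sum")).reset_index()
    total = pd.DataFrame([{
        "activity": "Total", "trials": len(df), "FP": int(df.fp.sum())}])
    out = pd.concat([grouped, total], ignore_index=True)
    out["fp_rate_pct"] = (100.0 * out.FP / out.trials).round(2)
    return out


def rolling_inference(
    trial: ImuTrial,
    model,
    windowing: WindowingConfig | None = None,
    madgwick: MadgwickConfig | None = None,
    threshold: float = 0.5,
) -> LeadTimeResult:
    """Forward rolling inference over one full fall trial.

    ``model`` needs ``predict_proba`` over ``(n, n_streams, 3, n_win)`` and
    may expose ``stream_indices`` to select an ablation subset.  The
    Madgwick state is continuous from the trial start (no per-window
    reinitialization) and no sample at or after ``impact_frame`` is read.
    """
    windowing = windowing or WindowingConfig()
    madgwick = madgwick or MadgwickConfig(dt=1.0 / windowing.fs)
    if trial.impact_frame is None:
        raise ValueError("rolling inference requires an untruncated fall trial")
    fs = trial.fs
    t_impact = trial.impact_frame / fs
    n_win, step = windowing.n_win, windowing.step
    last_end = trial.impact_frame - 1
    if last_end < n_win:
        return LeadTimeResult(trial.trial_id, t_impact, None, None,
                              reason="trial shorter than one window before impact")

    usable = trial.samples[: trial.impact_frame]
    filtered = butterworth_lowpass(usable, fs)
    seq = transform_sequence(filtered[:, :3], filtered[:, 3:], madgwick)

    ends = np.arange(n_win, last_end + 1, step)
    idx = getattr(model, "stream_indices", (0, 1, 2, 3))
    wins = np.stack([
        np.stack([
            seq.a_body[e - n_win:e].T, seq.w_body[e - n_win:e].T,
            seq.a_global[e - n_win:e].T, seq.w_global[e - n_win:e].T,
        ])[list(idx)]
        for e in ends
    ])
    probs = model.predict_proba(wins)[:, 1]
    above = np.nonzero(probs > threshold)[0]
    if above.size == 0:
        return LeadTimeResult(trial.trial_id, t_impact, None, None,
                              reason="probability never exceeded threshold")
    t_alarm = ends[above[0]] / fs
    return LeadTimeResult(trial.trial_id, t_impact, float(t_alarm),
                          float(t_impact - t_alarm))


def lead_time_summary(
    results: list[LeadTimeResult],
    compliance_ms: tuple[int, ...] = (100, 150, 200, 250),
) -> dict:
    """Detection rate, lead-time statistics and compliance rates.

    Missed trials count against the detection rate only; lead statistics
    and the ECDF are over detected trials.
    """
    if not results:
        raise ValueError("no rolling-inference results")
    leads = np.array([r.lead for r in results if r.detected], dtype=float)
    out = {
        "n_trials": len(results),
        "n_detected": int(leads.size),
        "detection_rate": leads.size / len(results),
    }
    if leads.size:
        leads_sorted = np.sort(leads)
        out.update({
            "median_lead_s": float(np.median(leads)),
            "mean_lead_s": float(np.mean(leads)),
            "compliance": {
                ms: float((leads >= ms / 1000.0).mean()) for ms in compliance_ms
            },
            "ecdf": (leads_sorted, np.arange(1, leads.size + 1) / leads.size),
        })
    return out


def plot_lead_times(results: list[LeadTimeResult], path) -> None:
    """Histogram + ECDF of detected lead times, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = lead_time_summary(results)
    leads_ms = np.array([r.lead for r in results if r.detected]) * 1000.0
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].hist(leads_ms, bins=20)
    axes[0].set_xlabel("lead time (ms)")
    axes[0].set_ylabel("trials")
    x, yv = summary["ecdf"]
    axes[1].step(x * 1000.0, yv, where="post")
    axes[1].set_xlabel("lead time (ms)")
    axes[1].set_ylabel("ECDF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
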