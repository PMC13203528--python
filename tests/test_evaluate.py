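"""Metrics, max-voting, FP analysis and rolling-inference lead times."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import confusion_matrix

from fallsense.evaluate import (
    LeadTimeResult,
    lead_time_summary,
    per_activity_fp,
    rolling_inference,
    trial_max_voting,
    window_metrics,
)
from fallsense.preprocess import ImuTrial, WindowingConfig


class ConstantModel:
    """Stub classifier emitting a fixed fall probability for every window."""

    stream_indices = (0, 1, 2, 3)

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.tile([1 - self.p, self.p], (X.shape[0], 1))


class GyroBurstModel:
    """Fires when any body-gyro sample in the window exceeds a rate threshold."""

    stream_indices = (0, 1, 2, 3)

    def __init__(self, thresh_dps=200.0):
        self.t = thresh_dps

    def predict_proba(self, X):
        hot = (np.abs(X[:, 1]) > self.t).any(axis=(1, 2))
        return np.column_stack([1.0 - hot, hot.astype(float)])


class TestWindowMetrics:
    def test_perfect_predictions(self):
        m = window_metrics(np.array([0.9, 0.1, 0.8, 0.2]), np.array([1, 0, 1, 0]))
        assert all(m[k] == 1.0 for k in ("accuracy", "recall", "specificity",
                                         "precision", "f1"))

    def test_all_negative_predictions(self):
        m = window_metrics(np.zeros(4), np.array([1, 0, 1, 0]))
        assert m["recall"] == 0.0 and m["specificity"] == 1.0 and m["f1"] == 0.0

    def test_printed_count_example(self):
        # TP=8, FP=2, FN=1, TN=9
        probs = np.array([0.9] * 8 + [0.9] * 2 + [0.1] * 1 + [0.1] * 9)
        labels = np.array([1] * 8 + [0] * 2 + [1] * 1 + [0] * 9)
        m = window_metrics(probs, labels)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(8 / 9)
        assert m["f1"] == pytest.approx(2 * (0.8 * 8 / 9) / (0.8 + 8 / 9))

    def test_counts_match_sklearn_on_random_vectors(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            probs = rng.random(n)
            labels = rng.integers(0, 2, n)
            m = window_metrics(probs, labels)
            tn, fp, fn, tp = confusion_matrix(
                labels, probs >= 0.5, labels=[0, 1]).ravel()
            assert (m["TP"], m["TN"], m["FP"], m["FN"]) == (tp, tn, fp, fn)
            assert m["TP"] + m["TN"] + m["FP"] + m["FN"] == n

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            window_metrics(np.array([]), np.array([]))

    def test_threshold_sweep_monotonicity(self, rng):
        probs = rng.random(200)
        labels = rng.integers(0, 2, 200)
        prev_rec, prev_spe = 1.1, -0.1
        for th in np.linspace(0.05, 0.95, 10):
            m = window_metrics(probs, labels, threshold=th)
            assert m["recall"] <= prev_rec + 1e-12
            assert m["specificity"] >= prev_spe - 1e-12
            prev_rec, prev_spe = m["recall"], m["specificity"]


class TestTrialMaxVoting:
    def test_single_hot_window_detects_trial(self):
        probs = np.array([0.1] * 9 + [0.9])
        ids = np.array(["t1"] * 10)
        labels = np.array([0] * 9 + [1])
        m, per = trial_max_voting(probs, ids, labels)
        assert m["recall"] == 1.0
        assert bool(per.decision.iloc[0])

    def test_threshold_inclusive_at_half(self):
        m, per = trial_max_voting(np.array([0.5]), np.array(["t1"]), np.array([1]))
        assert bool(per.decision.iloc[0])  # score == 0.5 counts as fall

    def test_recall_dominates_window_level(self, rng):
        # max-voting recall is never below window recall on the same scores
        for _ in range(20):
            n = int(rng.integers(10, 80))
            probs = rng.random(n)
            ids = rng.integers(0, 6, n).astype(str)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0 or labels.sum() == n:
                continue
            wm = window_metrics(probs, labels)
            tm, _ = trial_max_voting(probs, ids, labels)
            assert tm["recall"] >= wm["recall"] - 1e-12

    def test_missing_expected_trial_rejected(self):
        with pytest.raises(ValueError, match="zero windows"):
            trial_max_voting(np.array([0.4]), np.array(["t1"]), np.array([0]),
                             expected_trials=np.array(["t1", "t2"]))


class TestPerActivityFP:
    def test_printed_rate_example(self):
        # 13 false alarms among 159 trials of one activity -> 8.18%
        decisions = np.array([True] * 13 + [False] * 146)
        codes = np.array(["T10"] * 159)
        table = per_activity_fp(decisions, codes)
        row = table[table.activity == "T10"].iloc[0]
        assert row.trials == 159 and row.FP == 13
        assert row.fp_rate_pct == 8.18

    def test_zero_rate_group_and_total(self):
        decisions = np.array([False, False, True, False])
        codes = np.array(["T01", "T01", "T10", "T10"])
        table = per_activity_fp(decisions, codes)
        assert table[table.activity == "T01"].fp_rate_pct.iloc[0] == 0.0
        total = table[table.activity == "Total"].iloc[0]
        assert total.trials == 4 and total.FP == 1 and total.fp_rate_pct == 25.0

    def test_rates_recomputable_from_counts(self, rng):
        decisions = rng.random(300) < 0.05
        codes = rng.choice(["A", "B", "C"], 300)
        table = per_activity_fp(decisions, codes)
        recomputed = (100.0 * table.FP / table.trials).round(2)
        assert np.allclose(table.fp_rate_pct, recomputed)


def make_rolling_trial(n=1100, impact=1000, burst_start=None):
    """Level static trial; optional gyro burst marks the fall signature."""
    samples = np.zeros((n, 6))
    samples[:, 2] = 1.0
    if burst_start is not None:
        samples[burst_start:impact, 4] = 400.0  # pitch-rate burst, deg/s
    samples[impact:] = np.nan  # any read at/after impact would poison output
    return ImuTrial("S1", "F01", True, samples, onset_frame=impact - 60,
                    impact_frame=impact, trial_id="roll1")


class TestRollingInference:
    def test_always_positive_model_alarms_at_first_window(self):
        trial = make_rolling_trial()
        res = rolling_inference(trial, ConstantModel(1.0))
        assert res.detected
        assert res.t_alarm == pytest.approx(0.87)
        assert res.lead == pytest.approx(10.0 - 0.87)

    def test_always_negative_model_misses(self):
        res = rolling_inference(make_rolling_trial(), ConstantModel(0.0))
        assert not res.detected and res.lead is None
        assert "threshold" in res.reason

    def test_never_reads_at_or_after_impact(self):
        # post-impact samples are NaN; a finite prediction proves isolation
        res = rolling_inference(make_rolling_trial(), ConstantModel(1.0))
        assert res.detected

    def test_strictly_greater_threshold(self):
        res = rolling_inference(make_rolling_trial(), ConstantModel(0.5))
        assert not res.detected  # rolling alarm requires > 0.5

    def test_known_signature_onset_gives_expected_lead(self):
        cfg = WindowingConfig()
        burst = 940  # signature begins 600 ms before impact at sample 1000
        trial = make_rolling_trial(burst_start=burst)
        res = rolling_inference(trial, GyroBurstModel())
        # brute-force expectation: first window end covering the burst.
        # filtering smears the step by a few samples, so allow one sample
        ends = np.arange(cfg.n_win, trial.impact_frame, cfg.step)
        expected_end = ends[ends > burst][0]
        assert res.detected
        assert abs(res.t_alarm - expected_end / 100.0) <= cfg.step / 100.0
        assert res.lead <= (trial.impact_frame - burst) / 100.0

    def test_trial_shorter_than_window_is_missed_with_reason(self):
        samples = np.zeros((60, 6))
        samples[:, 2] = 1.0
        trial = ImuTrial("S1", "F01", True, samples, onset_frame=20,
                         impact_frame=60)
        res = rolling_inference(trial, ConstantModel(1.0))
        assert not res.detected and "shorter" in res.reason


class TestLeadTimeSummary:
    def test_all_missed(self):
        results = [LeadTimeResult("t", 5.0, None, None, "x") for _ in range(3)]
        s = lead_time_summary(results)
        assert s["detection_rate"] == 0.0 and "median_lead_s" not in s

    def test_median_and_compliance(self):
        results = [LeadTimeResult(f"t{i}", 5.0, 5.0 - l, l)
                   for i, l in enumerate([0.3, 0.4, 0.5])]
        s = lead_time_summary(results)
        assert s["median_lead_s"] == pytest.approx(0.4)
        assert s["compliance"][250] == 1.0
        x, y = s["ecdf"]
        assert y[-1] == 1.0 and x[-1] == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lead_time_summary([])

    def test_plot_writes_file(self, tmp_path):
        from fallsense.evaluate import plot_lead_times
        results = [LeadTimeResult(f"t{i}", 5.0, 4.6, 0.4) for i in range(4)]
        plot_lead_times(results, tmp_path / "lead.png")
        assert (tmp_path / "lead.png").stat().st_size > 0
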