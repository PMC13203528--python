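"""Subject-grouped cross-validated training of the dual-frame classifier.

The central object is :class:`DualFrameNetClassifier`, a scikit-learn style
estimator (``fit`` / ``predict`` / ``predict_proba`` / ``get_params``) whose
``X`` is the stacked window tensor ``(n, n_streams, 3, t)``.  The training
recipe is fixed: AdamW (lr 1e-3, weight decay 8e-5), cosine annealing with
warm restarts (T0 = 15 epochs, T_mult = 2, eta_min = 1e-6) stepped per
epoch, class-weighted cross-entropy with label smoothing 0.01, batch size
64, gradient clipping at global L2 norm 0.8, 105 epochs, seed 42.  No early
stopping or model selection: the final-epoch parameters are evaluated once.

Cross-validation is grouped by subject so no subject contributes windows to
both sides of any fold, and augmentation runs strictly after the split, on
the training windows only.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GroupKFold

from .attitude import MadgwickConfig
from .augment import AugmentConfig, augment_falls
from .evaluate import trial_max_voting, window_metrics
from .model import STREAM_SUBSETS, FallNet, ModelSpec
from .nn import AdamW, CosineWarmRestarts, clip_grad_norm, weighted_cross_entropy
from .preprocess import ImuTrial, WindowDataset, WindowingConfig, build_dataset

__all__ = [
    "TrainConfig",
    "DualFrameNetClassifier",
    "group_kfold_split",
    "class_weights",
    "train_fold",
    "run_cross_validation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """The fixed training recipe (defaults as used throughout)."""

    lr: float = 1e-3
    weight_decay: float = 8e-5
    t0: int = 15
    t_mult: int = 2
    eta_min: float = 1e-6
    label_smoothing: float = 0.01
    batch_size: int = 64
    epochs: int = 105
    grad_clip: float = 0.8
    seed: int = 42
    folds: int = 5


def group_kfold_split(trials: list[ImuTrial], k: int = 5):
    """Subject-grouped fold assignments over trials.

    Yields ``(train_idx, test_idx)`` pairs; every subject's trials land in
    exactly one test fold.  Raises when there are fewer subjects than folds.
    """
    subjects = np.asarray([t.subject_id for t in trials])
    if len(np.unique(subjects)) < k:
        raise ValueError("need at least as many subjects as folds")
    gkf = GroupKFold(n_splits=k)
    dummy = np.zeros(len(trials))
    return list(gkf.split(dummy, groups=subjects))


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1."""
    labels = np.asarray(labels)
    counts = np.array([(labels == 0).sum(), (labels == 1).sum()], dtype=float)
    if (counts == 0).any():
        raise ValueError("both classes must be present")
    w = labels.size / counts
    return w / w.mean()


class DualFrameNetClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style wrapper around the four-branch window classifier.

    Parameters mirror the training recipe; ``streams`` selects the full
    four-branch model ('all') or a two-branch ablation ('body' / 'global').
    ``X`` passed to :meth:`fit` must already be the stream subset matching
    ``streams`` — slice with :attr:`stream_indices` when ablating.

    Fitted attributes: ``model_`` (the network), ``classes_``, ``history_``
    (per-epoch learning rate and mean loss), ``class_weights_``.
    """

    def __init__(self, spec: ModelSpec | None = None, streams: str = "all",
                 epochs: int = 105, lr: float = 1e-3, weight_decay: float = 8e-5,
                 batch_size: int = 64, label_smoothing: float = 0.01,
                 grad_clip: float = 0.8, t0: int = 15, t_mult: int = 2,
                 eta_min: float = 1e-6, class_weighted: bool = True,
                 dtype: str = "float32", random_state: int = 42):
        self.spec = spec
        self.streams = streams
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.label_smoothing = label_smoothing
        self.grad_clip = grad_clip
        self.t0 = t0
        self.t_mult = t_mult
        self.eta_min = eta_min
        self.class_weighted = class_weighted
        self.dtype = dtype
        self.random_state = random_state

    @property
    def stream_indices(self) -> tuple[int, ...]:
        return STREAM_SUBSETS[self.streams]

    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n_br = len(STREAM_SUBSETS[self.streams])
        if X.ndim != 4 or X.shape[1] != n_br or X.shape[2] != 3:
            raise ValueError(
                f"X must be (n, {n_br}, 3, t) for streams={self.streams!r}; got {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if y is not None:
            y = np.asarray(y, dtype=np.int64)
            if y.shape != (X.shape[0],):
                raise ValueError("y must be one label per window")
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        self.classes_ = np.unique(y)
        weights = class_weights(y) if self.class_weighted else None
        self.class_weights_ = weights

        rng = np.random.default_rng(self.random_state)
        model = FallNet(self.spec, streams=self.streams, seed=self.random_state)
        dtype = np.dtype(self.dtype)
        model.cast(dtype)
        X = X.astype(dtype, copy=False)
        model.train()
        opt = AdamW(model.parameters(), lr=self.lr, weight_decay=self.weight_decay)
        sched = CosineWarmRestarts(opt, self.t0, self.t_mult, self.eta_min)

        n = X.shape[0]
        history = []
        for epoch in range(self.epochs):
            lr = sched.step(epoch)
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                logits = model(X[idx])
                loss, dlogits = weighted_cross_entropy(
                    logits, y[idx], weights, self.label_smoothing)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {start // self.batch_size}; "
                        f"lr={lr:.2e}")
                model.zero_grad()
                model.backward(dlogits.astype(dtype, copy=False))
                clip_grad_norm(model.parameters(), self.grad_clip)
                opt.step()
                losses.append(loss)
            history.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
        model.eval()
        self.model_ = model
        self.history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        X, _ = self._validate(X)
        # chunked inference keeps peak memory flat on long trials
        out = [self.model_.predict_proba(X[i:i + 256]) for i in range(0, X.shape[0], 256)]
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)


def train_fold(train_windows: WindowDataset, cfg: TrainConfig | None = None,
               spec: ModelSpec | None = None, streams: str = "all",
               ) -> tuple[DualFrameNetClassifier, list[dict]]:
    """Fit one fold with the fixed recipe; returns (estimator, epoch log)."""
    cfg = cfg or TrainConfig()
    clf = DualFrameNetClassifier(
        spec=spec, streams=streams, epochs=cfg.epochs, lr=cfg.lr,
        weight_decay=cfg.weight_decay, batch_size=cfg.batch_size,
        label_smoothing=cfg.label_smoothing, grad_clip=cfg.grad_clip,
        t0=cfg.t0, t_mult=cfg.t_mult, eta_min=cfg.eta_min,
        random_state=cfg.seed)
    idx = list(clf.stream_indices)
    clf.fit(train_windows.X[:, idx], train_windows.y)
    return clf, clf.history_


def run_cross_validation(
    trials: list[ImuTrial],
    windowing: WindowingConfig | None = None,
    madgwick: MadgwickConfig | None = None,
    augment: AugmentConfig | None = None,
    train_cfg: TrainConfig | None = None,
    spec: ModelSpec | None = None,
    streams: str = "all",
) -> dict:
    """Full subject-grouped K-fold protocol.

    Window extraction is per-trial and deterministic, so it runs once; folds
    are then taken over trials (grouped by subject) and augmentation is
    applied to each fold's training windows only.  Each trial is evaluated
    exactly once, in the single fold whose test side contains it.  Returns
    per-fold window- and trial-level metrics plus their across-fold means.
    """
    windowing = windowing or WindowingConfig()
    train_cfg = train_cfg or TrainConfig()
    augment = augment or AugmentConfig(seed=train_cfg.seed)
    dataset = build_dataset(trials, windowing, madgwick)
    splits = group_kfold_split(trials, train_cfg.folds)
    subj_by_trial = np.asarray([t.subject_id for t in trials])

    folds = []
    for fold_no, (tr_idx, te_idx) in enumerate(splits):
        tr_subj = set(subj_by_trial[tr_idx])
        te_subj = set(subj_by_trial[te_idx])
        if tr_subj & te_subj:
            raise RuntimeError(f"subject leakage across fold {fold_no}: {tr_subj & te_subj}")
        tr_mask = np.isin(dataset.subject_ids, list(tr_subj))
        te_mask = np.isin(dataset.subject_ids, list(te_subj))
        train_ds = augment_falls(dataset.subset(tr_mask, split="train"), augment)
        test_ds = dataset.subset(te_mask, split="test")

        clf, log = train_fold(train_ds, train_cfg, spec, streams)
        idx = list(clf.stream_indices)
        probs = clf.predict_proba(test_ds.X[:, idx])[:, 1]
        wm = window_metrics(probs, test_ds.y)
        tm, decisions = trial_max_voting(probs, test_ds.trial_ids, test_ds.y)
        folds.append({
            "fold": fold_no,
            "n_train_windows": len(train_ds),
            "n_test_windows": len(test_ds),
            "window": wm,
            "trial": tm,
            "decisions": decisions,
            "final_loss": log[-1]["loss"],
        })
        logger.info("fold %d: trial F1=%.4f window F1=%.4f",
                    fold_no, tm["f1"], wm["f1"])

    metric_keys = ("accuracy", "recall", "specificity", "precision", "f1")
    summary = {
        level: {k: float(np.mean([f[level][k] for f in folds])) for k in metric_keys}
        for level in ("window", "trial")
    }
    return {"folds": folds, "mean": summary, "streams": streams,
            "config": asdict(train_cfg)}
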