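"""Class-weighted cross-entropy with label smoothing, on raw logits."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "weighted_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray,
    targets: np.ndarray,
    class_weights: np.ndarray | None = None,
    smoothing: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Mean class-weighted smoothed cross-entropy and its logit gradient.

    The per-sample weight is the weight of the sample's true class, and the
    batch loss is normalized by the sum of weights (so uniform weights give
    the plain mean).  With smoothing ``s`` the target distribution is
    ``(1 - s) * onehot + s / K``.
    """
    n, k = logits.shape
    p = softmax(logits)
    t = np.full((n, k), smoothing / k)
    t[np.arange(n), targets] += 1.0 - smoothing
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=float)[targets]
    wsum = w.sum()
    logp = np.log(np.clip(p, 1e-300, None))
    loss = float(-(w[:, None] * t * logp).sum() / wsum)
    grad = w[:, None] * (p - t) / wsum
    return loss, grad
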