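"""Losses returning (scalar, gradient-w.r.t.-input) pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_dice_loss", "mse_loss"]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N,D,H,W) integer labels -> (N,K,D,H,W) float32 one-hot."""
    oh = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    idx = np.expand_dims(labels, 1)
    np.put_along_axis(oh, idx, 1.0, axis=1)
    return oh


def soft_dice(probs: np.ndarray, target_onehot: np.ndarray, eps: float = 1e-5
              ) -> np.ndarray:
    """Per-foreground-class soft Dice of batch-pooled volumes; shape (K-1,)."""
    axes = (0, 2, 3, 4)
    inter = (probs * target_onehot).sum(axis=axes)
    sums = probs.sum(axis=axes) + target_onehot.sum(axis=axes)
    d = (2.0 * inter + eps) / (sums + eps)
    return d[1:]


def softmax_dice_loss(logits: np.ndarray, labels: np.ndarray, eps: float = 1e-5
                      ) -> tuple[float, np.ndarray]:
    """Soft Dice loss over foreground classes, with gradient through softmax.

    ``logits``: (N,K,D,H,W); ``labels``: (N,D,H,W) integers in [0, K).
    Returns ``(loss, dloss/dlogits)``; loss = 1 - mean_c Dice_c over the
    foreground classes *present in the batch*.  Masking absent classes
    matters for patch-based training: a class missing from a patch would
    otherwise be driven to zero probability everywhere, which collapses
    small structures when patches are small.  A batch with no foreground at
    all yields zero loss and gradient.
    """
    if logits.shape[0] != labels.shape[0] or logits.shape[2:] != labels.shape[1:]:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs labels {labels.shape}")
    k = logits.shape[1]
    p = softmax(logits)
    t = one_hot(labels, k)
    axes = (0, 2, 3, 4)
    inter = (p * t).sum(axis=axes)
    t_sums = t.sum(axis=axes)
    sums = p.sum(axis=axes) + t_sums
    num = 2.0 * inter + eps
    den = sums + eps
    dice = num / den
    present = [c for c in range(1, k) if t_sums[c] > 0]
    if not present:
        return 0.0, np.zeros_like(p)
    loss = 1.0 - float(dice[present].mean())
    # d(dice_c)/d p_c(v) = (2 t_c(v) * den_c - num_c) / den_c^2
    dldp = np.zeros_like(p)
    for c in present:
        dldp[:, c] = -(2.0 * t[:, c] * den[c] - num[c]) / (den[c] ** 2 * len(present))
    # softmax backward
    inner = (dldp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dldp - inner)
    return loss, dlogits.astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean voxelwise cross-entropy; used to warm up Dice-loss training."""
    k = logits.shape[1]
    p = softmax(logits)
    t = one_hot(labels, k)
    n = labels.size
    loss = -float((t * np.log(p + 1e-9)).sum() / n)
    return loss, ((p - t) / n).astype(np.float32)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if pred.shape != target.shape:
        raise ValueError("prediction/target length mismatch")
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / pred.size) * diff
    return loss, grad.astype(np.float32)
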