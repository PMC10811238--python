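"""Focal loss for imbalanced binary classification.

With predicted positive-class probability ``p`` and ``p_t = p`` for label 1,
``1 - p`` for label 0, the per-sample loss is

    L = -alpha * (1 - p_t)**gamma * log(p_t)

averaged over the batch.  ``gamma = 0, alpha = 1`` recovers plain binary
cross-entropy; ``gamma > 0`` down-weights easy, confidently-classified
samples so the minority class dominates the gradient less.
"""

from __future__ import annotations

import numpy as np

__all__ = ["focal_loss", "focal_loss_grad", "P_FLOOR"]

P_FLOOR = 1e-7


def _pt(probabilities: np.ndarray, labels: np.ndarray) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pt = np.where(y == 1, p, 1.0 - p)
    return np.clip(pt, P_FLOOR, 1.0)


def focal_loss(probabilities, labels, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Mean focal loss of positive-class probabilities against 0/1 labels."""
    pt = _pt(probabilities, labels)
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))


def focal_loss_grad(probabilities, labels, alpha: float = 0.25, gamma: float = 2.0) -> np.ndarray:
    """d(mean loss)/d p, elementwise, for the positive-class probability p."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pt = _pt(p, y)
    one_minus = 1.0 - pt
    if gamma == 0:
        dl_dpt = -alpha / pt
    else:
        dl_dpt = alpha * (gamma * one_minus ** (gamma - 1.0) * np.log(pt) - one_minus**gamma / pt)
    sign = np.where(y == 1, 1.0, -1.0)
    return dl_dpt * sign / p.size
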