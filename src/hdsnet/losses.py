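"""Compound segmentation loss: soft Dice + binary cross-entropy.

The Dice term counters foreground/background class imbalance; the BCE term
keeps gradients well-behaved where the Dice ratio is flat. The total is the
plain sum of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossValue", "dice_loss", "bce_loss", "combined_loss", "combined_loss_with_grad", "sigmoid"]

_EPS = 1e-7


@dataclass
class LossValue:
    total: float
    dice_term: float
    bce_term: float


def _check(probs: np.ndarray, target: np.ndarray):
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    if probs.min() < 0.0 or probs.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def dice_loss(probs: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """1 − (2·Σ p·t + smooth) / (Σ p + Σ t + smooth), over all elements."""
    _check(probs, target)
    p = probs.astype(np.float64, copy=False)
    t = target.astype(np.float64, copy=False)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def bce_loss(probs: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy, probabilities clamped away from {0, 1}."""
    _check(probs, target)
    p = np.clip(probs.astype(np.float64, copy=False), _EPS, 1.0 - _EPS)
    t = target.astype(np.float64, copy=False)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def combined_loss(probs: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> LossValue:
    d = dice_loss(probs, target, smooth)
    b = bce_loss(probs, target)
    return LossValue(total=d + b, dice_term=d, bce_term=b)


def combined_loss_with_grad(logits: np.ndarray, target: np.ndarray, smooth: float = 1.0):
    """Loss on sigmoid(logits) and its gradient w.r.t. the logits.

    BCE is evaluated in the numerically safe logit form; the Dice gradient is
    chained through the sigmoid analytically.
    """
    if logits.shape != target.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {target.shape}")
    z = logits.astype(np.float64, copy=False)
    t = target.astype(np.float64, copy=False)
    p = sigmoid(z)

    n = z.size
    bce = float((np.logaddexp(0.0, z) - t * z).mean())
    dbce_dz = (p - t) / n

    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    num = 2.0 * inter + smooth
    den = denom + smooth
    dice = 1.0 - num / den
    # d/dp_i [ -num/den ] = -(2 t_i den - num) / den^2 ; chain by p(1-p)
    ddice_dp = -(2.0 * t * den - num) / (den * den)
    ddice_dz = ddice_dp * p * (1.0 - p)

    grad = (dbce_dz + ddice_dz).astype(np.float32)
    return LossValue(total=dice + bce, dice_term=dice, bce_term=bce), grad
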