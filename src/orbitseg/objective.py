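"""Focal Tversky training objective.

The Tversky index generalizes soft Dice by weighting false positives and
false negatives asymmetrically::

    TI = (sum(p*t) + eps) / (sum(p*t) + alpha*sum(p*(1-t)) + beta*sum((1-p)*t) + eps)

and the focal variant raises the complement to a power gamma::

    loss = (1 - TI) ** gamma

With ``alpha = beta = 0.5`` and ``gamma = 1`` the loss reduces to
``1 - soft Dice``.  Soft counts are aggregated over the whole batch (not
averaged per image), so small structures in one image still contribute.
The defaults ``alpha=0.7, beta=0.3, gamma=4/3`` follow the originating
focal-Tversky formulation and penalize false negatives harder, which suits
thin orbital structures such as the optic nerve and muscle bands.

An analytic gradient w.r.t. the probabilities is provided because the
training stack uses explicit backward passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TverskyParams",
    "soft_tversky_index",
    "focal_tversky_loss",
    "focal_tversky_grad",
]


@dataclass(frozen=True)
class TverskyParams:
    alpha: float = 0.7  # false-positive weight
    beta: float = 0.3  # false-negative weight
    gamma: float = 4.0 / 3.0  # focal exponent
    epsilon: float = 1e-6  # smoothing; defines the empty-empty limit TI -> 1

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _soft_counts(probs: np.ndarray, target: np.ndarray) -> tuple[float, float, float]:
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {target.shape}")
    tp = float(np.sum(probs * target))
    fp = float(np.sum(probs * (1.0 - target)))
    fn = float(np.sum((1.0 - probs) * target))
    return tp, fp, fn


def soft_tversky_index(
    probs: np.ndarray, target: np.ndarray, params: TverskyParams = TverskyParams()
) -> float:
    """Batch-aggregated soft Tversky index in [0, 1]."""
    tp, fp, fn = _soft_counts(probs, target)
    num = tp + params.epsilon
    den = tp + params.alpha * fp + params.beta * fn + params.epsilon
    return num / den


def focal_tversky_loss(
    probs: np.ndarray, target: np.ndarray, params: TverskyParams = TverskyParams()
) -> float:
    """Focal Tversky loss ``(1 - TI) ** gamma`` in [0, 1]."""
    ti = soft_tversky_index(probs, target, params)
    return (1.0 - ti) ** params.gamma


def focal_tversky_grad(
    probs: np.ndarray, target: np.ndarray, params: TverskyParams = TverskyParams()
) -> np.ndarray:
    """Gradient of the focal Tversky loss w.r.t. each probability.

    With I = sum(p*t) and D = I + alpha*sum(p*(1-t)) + beta*sum((1-p)*t),
    TI = (I+eps)/(D+eps) and

        dTI/dp_i = [t_i*(D+eps) - (I+eps)*(t_i + alpha*(1-t_i) - beta*t_i)]
                   / (D+eps)^2
        dL/dp_i  = -gamma * (1-TI)^(gamma-1) * dTI/dp_i
    """
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    tp, fp, fn = _soft_counts(p, t)
    num = tp + params.epsilon
    den = tp + params.alpha * fp + params.beta * fn + params.epsilon
    ti = num / den
    # dI/dp_i = t_i ; dD/dp_i = t_i + alpha*(1-t_i) - beta*t_i
    d_den = t + params.alpha * (1.0 - t) - params.beta * t
    dti = (t * den - num * d_den) / (den * den)
    one_minus = max(1.0 - ti, 0.0)
    dl_dti = -params.gamma * one_minus ** (params.gamma - 1.0)
    return dl_dti * dti
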