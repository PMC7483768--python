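"""Training and model-selection objectives.

The training loss is a class-weighted soft-Dice overlap, negated so that
perfect overlap gives -1 (the sum of class weights).  For a batch of P
reference/prediction pairs (y, yhat), with class weights w_l and a small
epsilon guarding only the denominator:

    L_D = -(1/P) sum_p sum_l w_l * 2 sum_i y yhat / (sum_i (y + yhat) + eps)

A complementary negative pixel-specificity loss penalizes false positives:

    L_S = -(1/P) sum_p sum_l w_l * sum_i (1-y)(1-yhat) / (sum_i (1-yhat) + eps)

Checkpoint selection uses the convex combination V = alpha*L_D + (1-alpha)*L_S
evaluated on a validation set; alpha = 1 reduces V to the Dice loss exactly.

All functions accept (N, L, h, w) arrays and optionally return the analytic
gradient with respect to yhat, used by the SGD trainer.  A class absent from
both y and yhat contributes 0 to the Dice term (the formula taken literally),
not a perfect score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import LabelSet


@dataclass(frozen=True)
class LossConfig:
    """Class weights, denominator guard and the V mixing weight alpha."""

    weights: tuple[float, ...]
    epsilon: float = 1e-5
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @classmethod
    def from_labelset(cls, labelset: LabelSet, epsilon: float = 1e-5,
                      alpha: float = 1.0) -> "LossConfig":
        return cls(weights=tuple(labelset.weights), epsilon=epsilon, alpha=alpha)

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


def _check_shapes(y: np.ndarray, yhat: np.ndarray, cfg: LossConfig) -> None:
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs yhat {yhat.shape}")
    if y.ndim != 4 or y.shape[1] != len(cfg.weights):
        raise ValueError(
            f"expected (N, {len(cfg.weights)}, h, w) tensors, got {y.shape}")


def dice_loss(y: np.ndarray, yhat: np.ndarray, cfg: LossConfig,
              return_grad: bool = False):
    """Negative class-weighted soft-Dice of a batch; in [-1, 0].

    With ``return_grad`` also returns dL/dyhat of the same shape as yhat.
    Computation runs in the floating dtype of ``yhat`` (accumulations in
    float64); pass float64 inputs for oracle-grade precision.
    """
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.dtype != yhat.dtype:
        y = y.astype(yhat.dtype)
    _check_shapes(y, yhat, cfg)
    n = y.shape[0]
    w = cfg.weight_array[None, :]
    inter = (y * yhat).sum(axis=(2, 3), dtype=np.float64)    # (N, L)
    denom = (y + yhat).sum(axis=(2, 3), dtype=np.float64) + cfg.epsilon
    loss = -(w * 2.0 * inter / denom).sum() / n
    if not return_grad:
        return float(loss)
    # d/dyhat_i of 2*inter/denom = (2*y_i*denom - 2*inter) / denom^2
    coef = -(w / n)
    a = (2.0 * coef / denom).astype(yhat.dtype)
    b = (2.0 * coef * inter / denom ** 2).astype(yhat.dtype)
    grad = y * a[..., None, None] - b[..., None, None]
    return float(loss), grad


def specificity_loss(y: np.ndarray, yhat: np.ndarray, cfg: LossConfig,
                     return_grad: bool = False):
    """Negative class-weighted mean pixel specificity of a batch; in [-1, 0]."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.dtype != yhat.dtype:
        y = y.astype(yhat.dtype)
    _check_shapes(y, yhat, cfg)
    n = y.shape[0]
    w = cfg.weight_array[None, :]
    u = 1.0 - y
    v = 1.0 - yhat
    num = (u * v).sum(axis=(2, 3), dtype=np.float64)         # (N, L)
    denom = v.sum(axis=(2, 3), dtype=np.float64) + cfg.epsilon
    loss = -(w * num / denom).sum() / n
    if not return_grad:
        return float(loss)
    # d/dv_i of num/denom = (u_i*denom - num)/denom^2 ; dv/dyhat = -1
    coef = (w / n)
    a = (coef / denom).astype(yhat.dtype)
    b = (coef * num / denom ** 2).astype(yhat.dtype)
    grad = u * a[..., None, None] - b[..., None, None]
    return float(loss), grad


def selection_metric(y: np.ndarray, yhat: np.ndarray, cfg: LossConfig,
                     alpha: float | None = None) -> float:
    """Checkpoint-selection metric V = alpha*L_D + (1-alpha)*L_S (lower is better)."""
    a = cfg.alpha if alpha is None else alpha
    if not 0.0 <= a <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if a == 1.0:
        return dice_loss(y, yhat, cfg)
    if a == 0.0:
        return specificity_loss(y, yhat, cfg)
    return a * dice_loss(y, yhat, cfg) + (1.0 - a) * specificity_loss(y, yhat, cfg)
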