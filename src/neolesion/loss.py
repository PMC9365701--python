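"""Hybrid training loss: smoothed dice loss plus 1x binary focal loss.

Segmenting new lesions is an extremely class-imbalanced problem — lesion
pixels are a tiny fraction of each slice. The dice term optimizes overlap
directly and is insensitive to the background majority; the focal term
down-weights easy pixels by ``(1 - p_t)^gamma`` so the gradient concentrates
on hard ones. The total is ``dice + focal_weight * focal`` with
``focal_weight = 1``.

As configured here the balance weight ``alpha`` multiplies both the positive
and the negative focal term:

    focal = mean( -gt * alpha * (1-pr)^gamma * log(pr)
                  - (1-gt) * alpha * pr^gamma * log(1-pr) )

The standard formulation, with ``1 - alpha`` on the negative class, is
available via ``alpha_complement=True``.

All functions accept either numpy arrays (returning floats) or autograd
tensors (returning tensors, for training). With ``batch_axis=0`` dice is
computed per sample and averaged; the focal mean is always over all pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Tensor
from .nn import autograd as ag


@dataclasses.dataclass(frozen=True)
class LossParams:
    alpha: float = 0.25
    gamma: float = 2.0
    smooth: float = 1.0
    focal_weight: float = 1.0
    epsilon: float = 1e-7
    alpha_complement: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1): {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0: {self.gamma}")
        if self.smooth <= 0:
            raise ValueError(f"smooth must be > 0: {self.smooth}")
        if not 0 < self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in (0, 0.5): {self.epsilon}")


def _prepare(gt, pr):
    gt_t = gt if isinstance(gt, Tensor) else Tensor(np.asarray(gt, dtype=float))
    pr_t = pr if isinstance(pr, Tensor) else Tensor(np.asarray(pr, dtype=float))
    if gt_t.shape != pr_t.shape:
        raise ValueError(f"shape mismatch: gt {gt_t.shape} vs pr {pr_t.shape}")
    return gt_t, pr_t, isinstance(pr, Tensor) or isinstance(gt, Tensor)


def _maybe_item(value: Tensor, tensor_in: bool):
    return value if tensor_in else value.item()


def dice_loss(gt, pr, smooth: float = 1.0, batch_axis: int | None = None):
    """``1 - (2*sum(gt*pr) + smooth) / (sum(gt) + sum(pr) + smooth)``.

    With ``batch_axis=0`` the loss is evaluated per sample over the
    remaining axes and averaged.
    """
    gt_t, pr_t, tensor_in = _prepare(gt, pr)
    if batch_axis is None:
        axes = None
    else:
        axes = tuple(i for i in range(len(gt_t.shape)) if i != batch_axis)
    inter = ag.reduce_sum(ag.mul(gt_t, pr_t), axis=axes)
    denom = ag.add(ag.add(ag.reduce_sum(gt_t, axis=axes),
                          ag.reduce_sum(pr_t, axis=axes)), smooth)
    dice = ag.mul(ag.add(ag.mul(inter, 2.0), smooth), ag.power(denom, -1.0))
    loss = ag.add(1.0, ag.neg(ag.reduce_mean(dice)))
    return _maybe_item(loss, tensor_in)


def binary_focal_loss(gt, pr, alpha: float = 0.25, gamma: float = 2.0,
                      epsilon: float = 1e-7, alpha_complement: bool = False):
    """Mean focal loss over all pixels, with ``pr`` clamped for log stability."""
    gt_t, pr_t, tensor_in = _prepare(gt, pr)
    pr_c = ag.clip(pr_t, epsilon, 1.0 - epsilon)
    one_minus_pr = ag.add(1.0, ag.neg(pr_c))
    one_minus_gt = ag.add(1.0, ag.neg(gt_t))
    neg_alpha = (1.0 - alpha) if alpha_complement else alpha
    pos = ag.mul(ag.mul(ag.mul(gt_t, alpha),
                        ag.power(one_minus_pr, gamma)), ag.log(pr_c))
    neg = ag.mul(ag.mul(ag.mul(one_minus_gt, neg_alpha),
                        ag.power(pr_c, gamma)), ag.log(one_minus_pr))
    loss = ag.neg(ag.reduce_mean(ag.add(pos, neg)))
    return _maybe_item(loss, tensor_in)


def total_loss(gt, pr, params: LossParams = LossParams(),
               batch_axis: int | None = None):
    """``dice_loss + focal_weight * binary_focal_loss``."""
    gt_t, pr_t, tensor_in = _prepare(gt, pr)
    d = dice_loss(gt_t, pr_t, smooth=params.smooth, batch_axis=batch_axis)
    f = binary_focal_loss(gt_t, pr_t, alpha=params.alpha, gamma=params.gamma,
                          epsilon=params.epsilon,
                          alpha_complement=params.alpha_complement)
    loss = ag.add(d, ag.mul(f, params.focal_weight))
    return _maybe_item(loss, tensor_in)


def dice_score(gt: np.ndarray, pr_binary: np.ndarray,
               smooth: float = 1.0) -> float:
    """Smoothed dice similarity of a binarized prediction (monitoring metric)."""
    gt = np.asarray(gt, dtype=float)
    pr_binary = np.asarray(pr_binary, dtype=float)
    inter = float((gt * pr_binary).sum())
    return (2.0 * inter + smooth) / (gt.sum() + pr_binary.sum() + smooth)
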