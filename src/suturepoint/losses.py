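"""Supervised objectives for the two-stage detector.

Stage 1 (the Gaussian-filtered heatmap) is always trained against the
distribution-encoded ground truth with ``L1 = MSE + 1 - SDC``, where SDC is
the soft Sorensen-Dice coefficient.  Stage 2 (after the soft-argmax NMS)
is trained either against the same heatmap target with the same loss
(variant 1) or against the binary point mask with ``1 - F_beta`` (variant 2);
with ``beta = 2`` the F-beta score weighs recall four times precision, which
penalises false negatives under the extreme foreground/background imbalance
of single-pixel targets.  The joint objective is the unweighted sum
``L1 + L2``.

All functions accept either plain numpy arrays or autograd tensors and
return an autograd :class:`~suturepoint.autograd.Tensor` scalar (use
``.item()`` for the float value); gradients flow when the inputs carry them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import StageOutputs

__all__ = [
    "LossConfig",
    "mse",
    "soft_dice",
    "heatmap_loss",
    "f_beta_score",
    "total_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss selection: ``variant`` 1 or 2, F-beta ``beta``, smoothing ``epsilon``."""

    variant: int = 1
    beta: float = 2.0
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _pair(pred, target) -> tuple[Tensor, Tensor]:
    pred = pred if isinstance(pred, Tensor) else ag.tensor(np.asarray(pred))
    target = target if isinstance(target, Tensor) else ag.tensor(np.asarray(target))
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return pred, target


def mse(pred, target) -> Tensor:
    """Mean over all pixels of the squared difference."""
    pred, target = _pair(pred, target)
    return ((pred - target) ** 2).mean()


def soft_dice(pred, target, epsilon: float = 1e-6) -> Tensor:
    """Soft Sorensen-Dice coefficient ``(2 sum(p g) + eps) / (sum p + sum g + eps)``.

    The smoothing ``epsilon`` makes the empty-target case well defined
    (score 1 when both maps are empty).
    """
    pred, target = _pair(pred, target)
    num = 2.0 * (pred * target).sum() + epsilon
    den = pred.sum() + target.sum() + epsilon
    return num / den


def heatmap_loss(pred, target, epsilon: float = 1e-6) -> Tensor:
    """Stage loss ``MSE + 1 - SDC`` against a heatmap target."""
    return mse(pred, target) + 1.0 - soft_dice(pred, target, epsilon)


def f_beta_score(pred, target, beta: float = 2.0, epsilon: float = 1e-6) -> Tensor:
    """Soft F-beta score between a [0, 1] prediction and a binary mask.

    ``((1 + b^2) sum(p g) + eps) /
    ((1 + b^2) sum(p g) + b^2 sum((1 - p) g) + sum(p (1 - g)) + eps)``;
    with ``beta = 1`` this reduces exactly to the soft Dice coefficient.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    pred, target = _pair(pred, target)
    b2 = beta * beta
    tp = (pred * target).sum()
    fn = ((1.0 - pred) * target).sum()
    fp = (pred * (1.0 - target)).sum()
    num = (1.0 + b2) * tp + epsilon
    den = (1.0 + b2) * tp + b2 * fn + fp + epsilon
    return num / den


def total_loss(outputs: StageOutputs, heatmap_target, binary_target,
               config: LossConfig = LossConfig()) -> Tensor:
    """Joint objective ``L1 + L2`` over both output stages.

    ``L1`` is always :func:`heatmap_loss` on stage 1.  ``L2`` is
    :func:`heatmap_loss` on stage 2 for variant 1, or ``1 - F_beta`` against
    the binary mask for variant 2.
    """
    l1 = heatmap_loss(outputs.stage1, heatmap_target, config.epsilon)
    if config.variant == 1:
        l2 = heatmap_loss(outputs.stage2, heatmap_target, config.epsilon)
    else:
        l2 = 1.0 - f_beta_score(outputs.stage2, binary_target,
                                config.beta, config.epsilon)
    return l1 + l2
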