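"""Training objectives: spread loss (capsule nets) and generalized Dice loss.

The spread loss pushes the true-class activation above every wrong-class
activation by a margin that is ramped up during training; the generalized
Dice loss weights each class by the squared reciprocal of its volume so
small structures (the lumen, the thin vessel wall) are not swamped by the
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor

__all__ = ["MarginSchedule", "margin_at", "spread_loss", "generalized_dice_loss"]


@dataclass(frozen=True)
class MarginSchedule:
    """Linear ramp of the spread-loss margin.

    Starting small keeps early gradients alive when all activations are
    similar; the margin then grows linearly over ``ramp_epochs`` and stays
    at ``end_margin``.  The default ramps 0.2 -> 0.9 over the first fifth
    of a 200-epoch schedule.
    """

    start_margin: float = 0.2
    end_margin: float = 0.9
    ramp_epochs: int = 40

    def __post_init__(self):
        if not (0 < self.start_margin < 1):
            raise ValueError("start_margin must lie in (0, 1)")
        if not (0 < self.end_margin <= 1):
            raise ValueError("end_margin must lie in (0, 1]")
        if self.start_margin > self.end_margin:
            raise ValueError("start_margin must not exceed end_margin")
        if self.ramp_epochs < 1:
            raise ValueError("ramp_epochs must be >= 1")


def margin_at(schedule: MarginSchedule, epoch: int) -> float:
    """Margin for a given epoch: linear from start to end over the ramp."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch >= schedule.ramp_epochs:
        return schedule.end_margin
    frac = epoch / schedule.ramp_epochs
    return schedule.start_margin + frac * (schedule.end_margin - schedule.start_margin)


def _one_hot(target: np.ndarray, classes: int) -> np.ndarray:
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= classes:
        raise ValueError(
            f"target contains class indices outside [0, {classes - 1}]")
    return np.eye(classes, dtype=np.float32)[target]


def spread_loss(activations, target, margin: float):
    """Margin loss on raw class activations.

    Per pixel with true class ``t``:
    ``sum_{c != t} max(0, margin - (a_t - a_c))**2``, averaged over pixels.
    Activations enter unnormalized, exactly as produced by the
    Frobenius-norm-product output layer.
    """
    if not (0 < margin <= 1):
        raise ValueError("margin must lie in (0, 1]")
    acts = astensor(activations)
    h, w, classes = acts.shape
    onehot = _one_hot(target, classes)
    if onehot.shape[:2] != (h, w):
        raise ValueError("activations and target shapes disagree")
    a_t = ad.tsum(acts * onehot, axis=-1, keepdims=True)
    hinge = ad.relu(margin - (a_t - acts))
    penal = ad.square(hinge) * (1.0 - onehot)   # wrong classes only
    return ad.tsum(penal) / float(h * w)


def generalized_dice_loss(probabilities, target):
    """One minus the generalized Dice overlap.

    ``1 - 2 * (sum_c w_c sum_n p_cn g_cn) / (sum_c w_c sum_n (p_cn + g_cn))``
    with ``w_c = 1 / (sum_n g_cn)**2``.  Classes absent from the target get
    their weight capped at the largest finite class weight so the loss stays
    defined.  Probabilities must sum to 1 per pixel.
    """
    probs = astensor(probabilities)
    h, w, classes = probs.shape
    sums = probs.data.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("probabilities must sum to 1 per pixel")
    onehot = _one_hot(target, classes)
    if onehot.shape[:2] != (h, w):
        raise ValueError("probabilities and target shapes disagree")
    volumes = onehot.reshape(-1, classes).sum(axis=0)
    with np.errstate(divide="ignore"):
        weights = 1.0 / volumes ** 2
    if np.isinf(weights).all():
        weights = np.ones_like(weights)
    else:
        weights[np.isinf(weights)] = weights[np.isfinite(weights)].max()
    weights = weights.astype(probs.dtype)
    intersect = ad.tsum(probs * onehot, axis=(0, 1))
    cardinality = ad.tsum(probs, axis=(0, 1)) + volumes
    numer = 2.0 * ad.tsum(intersect * weights)
    denom = ad.tsum(cardinality * weights)
    return 1.0 - numer / denom

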