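"""The composite generator objective.

Three ingredients, combined as ``total = adv + λ1·L1 + λ2·cross``:

* an adversarial term over the patch discriminator's fake scores — either
  the non-saturating log form ``−mean log D(x, G(x))`` or the least-squares
  form ``½·mean (D(x, G(x)) − 1)²``;
* an L1 reconstruction term, the mean absolute difference between the
  translated image and the target;
* a pixel-wise binary cross-entropy consistency term between a reference
  image (the target by default) and the synthetic image, averaged over all
  pixels and channels.  Setting λ2 = 0 removes it, which is the ablated
  variant of the objective.

Defaults λ1 = 100 and λ2 = 10.  All formulas run unchanged on ndarrays
(returning floats) or autodiff Tensors (returning graph nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dispatch as D
from .discriminator import PatchScores, _scores_array
from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 100.0  # L1 weight
    lambda2: float = 10.0   # cross-entropy consistency weight

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ParameterError("loss weights must be nonnegative")


@dataclass
class LossBreakdown:
    """adv + lambda1·l1 + lambda2·cross = total (fields may be Tensors
    during training; floats otherwise)."""

    adv: object
    l1: object
    cross: object
    total: object

    def as_floats(self) -> "LossBreakdown":
        return LossBreakdown(*(D.to_float(v) for v in
                               (self.adv, self.l1, self.cross, self.total)))


def generator_adversarial_loss(scores_fake, mode: str = "log"):
    """Generator-side adversarial term from the fake patch scores.

    log mode uses the non-saturating form −mean log D(fake); lsgan mode is
    ½·mean (D(fake) − 1)².
    """
    fake = _scores_array(scores_fake)
    if (isinstance(fake, np.ndarray) and fake.size == 0):
        raise ValidationError("empty score set")
    if mode == "log":
        return -1.0 * D.mean(D.log(D.clamp(fake)))
    if mode == "lsgan":
        return 0.5 * D.mean(D.square(fake - 1.0))
    raise ValidationError(f"unknown adversarial mode {mode!r}")


def l1_loss(target, synthetic):
    """Mean absolute difference over all pixels and channels."""
    if _shape(target) != _shape(synthetic):
        raise ValidationError(
            f"shape mismatch: {_shape(target)} vs {_shape(synthetic)}")
    return D.mean(D.absolute(target - synthetic))


def cross_entropy_consistency(reference, synthetic):
    """Pixel-wise BCE −mean[r·log s + (1−r)·log(1−s)].

    ``reference`` must lie in [0, 1]; ``synthetic`` is clamped away from the
    endpoints before the logs.
    """
    if _shape(reference) != _shape(synthetic):
        raise ValidationError(
            f"shape mismatch: {_shape(reference)} vs {_shape(synthetic)}")
    s = D.clamp(synthetic)
    r = reference
    return -1.0 * D.mean(r * D.log(s) + (1.0 - r) * D.log(1.0 - s))


def total_generator_loss(scores_fake, target, synthetic,
                         weights: LossWeights | None = None,
                         mode: str = "log",
                         ce_reference=None) -> LossBreakdown:
    """Weighted composite objective; ``ce_reference`` defaults to the target."""
    if weights is None:
        weights = LossWeights()
    adv = generator_adversarial_loss(scores_fake, mode)
    l1 = l1_loss(target, synthetic)
    if weights.lambda2 > 0:
        ref = target if ce_reference is None else ce_reference
        cross = cross_entropy_consistency(ref, synthetic)
    else:
        cross = 0.0
    total = adv + weights.lambda1 * l1 + weights.lambda2 * cross
    return LossBreakdown(adv=adv, l1=l1, cross=cross, total=total)


def _shape(x):
    return tuple(x.shape)
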