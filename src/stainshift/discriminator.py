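"""Patch-grid discriminator.

The candidate image is partitioned into an explicit rows×cols grid of
non-overlapping patches (default 4×4 — sixteen patches).  Every patch is
scored independently by one shared convolutional encoder ending in a
sigmoid, and the discriminator's verdict for the whole image is the
arithmetic mean of the per-patch probabilities.  In conditional mode
(the default) the encoder sees the aligned source patch concatenated
channel-wise with the candidate patch, so "real" means "a plausible
source→target pairing", not merely "a plausible target".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from . import _dispatch as D
from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class PatchGridSpec:
    grid: tuple = (4, 4)
    encoder_depth: int = 2
    base_channels: int = 16
    conditional: bool = True

    def __post_init__(self):
        r, c = self.grid
        if r < 1 or c < 1:
            raise ConfigurationError("grid must be at least 1×1")
        if self.encoder_depth < 1:
            raise ConfigurationError("encoder_depth must be >= 1")


@dataclass
class PatchScores:
    """Per-patch probabilities (rows×cols) and their arithmetic mean."""

    per_patch: np.ndarray
    aggregate: float

    @staticmethod
    def from_grid(per_patch: np.ndarray) -> "PatchScores":
        per_patch = np.asarray(per_patch, dtype=np.float64)
        return PatchScores(per_patch=per_patch,
                           aggregate=float(per_patch.mean()))


def extract_patches(image: np.ndarray, grid=(4, 4)) -> list:
    """Partition an H×W×C image into rows·cols tiles, raster order."""
    rows, cols = grid
    h, w = image.shape[:2]
    if h % rows or w % cols:
        raise ConfigurationError(
            f"image {h}×{w} not divisible by grid {rows}×{cols}")
    ph, pw = h // rows, w // cols
    return [image[r * ph:(r + 1) * ph, c * pw:(c + 1) * pw]
            for r in range(rows) for c in range(cols)]


def _patch_batch(x, grid):
    """(N,C,H,W) Tensor -> (N·rows·cols, C, ph, pw) Tensor, raster order."""
    rows, cols = grid
    n, c, h, w = x.shape
    if h % rows or w % cols:
        raise ConfigurationError(
            f"image {h}×{w} not divisible by grid {rows}×{cols}")
    ph, pw = h // rows, w // cols
    x = nn.reshape(x, (n, c, rows, ph, cols, pw))
    x = nn.transpose(x, (0, 2, 4, 1, 3, 5))
    return nn.reshape(x, (n * rows * cols, c, ph, pw))


class PatchDiscriminator(nn.Module):
    """Shared patch encoder: strided convs → 1×1 head → spatial mean → sigmoid."""

    def __init__(self, spec: PatchGridSpec, seed: int):
        super().__init__()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        cin = 6 if spec.conditional else 3
        ch = spec.base_channels
        self.stem = nn.Conv2d(cin, ch, 3, rng)
        for i in range(1, spec.encoder_depth + 1):
            cout = min(ch * 2 ** i, 4 * ch)
            setattr(self, f"down{i}",
                    nn.Conv2d(min(ch * 2 ** (i - 1), 4 * ch), cout, 3, rng, stride=2))
        self.head = nn.Conv2d(min(ch * 2 ** spec.encoder_depth, 4 * ch), 1, 1, rng)

    # -- differentiable paths ------------------------------------------------
    def encode_patches(self, patches):
        """(P, C, ph, pw) Tensor -> (P,) Tensor of probabilities."""
        ph = patches.shape[2]
        if ph % (2 ** self.spec.encoder_depth):
            raise ConfigurationError(
                f"patch size {ph} not divisible by 2^encoder_depth "
                f"= {2 ** self.spec.encoder_depth}")
        h = nn.leaky_relu(self.stem(patches), 0.2)
        for i in range(1, self.spec.encoder_depth + 1):
            h = nn.leaky_relu(getattr(self, f"down{i}")(h), 0.2)
        logits = nn.tmean(self.head(h), axis=(1, 2, 3))
        return nn.sigmoid(logits)

    def forward(self, source, candidate):
        """(N,C,H,W) Tensors -> (N·rows·cols,) Tensor of patch probabilities."""
        if self.spec.conditional:
            if source is None:
                raise ValidationError("conditional discriminator needs the source")
            if source.shape != candidate.shape:
                raise ValidationError(
                    f"source/candidate shape mismatch: {source.shape} vs {candidate.shape}")
            stacked = nn.concat([source, candidate], axis=1)
        else:
            stacked = candidate
        return self.encode_patches(_patch_batch(stacked, self.spec.grid))


def build_discriminator(spec: PatchGridSpec, seed: int) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed)


def score_patch(disc: PatchDiscriminator, patch: np.ndarray,
                source_patch: np.ndarray | None = None) -> float:
    """Probability in (0, 1) that one H×W×C patch (pair) is real."""
    if disc.spec.conditional:
        if source_patch is None:
            raise ValidationError("conditional discriminator needs source_patch")
        if source_patch.shape != patch.shape:
            raise ValidationError("patch shape mismatch")
        stacked = np.concatenate([source_patch, patch], axis=2)
    else:
        stacked = patch
    x = stacked.transpose(2, 0, 1)[None]
    with nn.no_grad():
        p = disc.encode_patches(nn.Tensor(x)).data
    return float(p[0])


def discriminate(disc: PatchDiscriminator, source: np.ndarray,
                 candidate: np.ndarray) -> PatchScores:
    """Score every grid patch of an H×W×3 candidate; aggregate = mean."""
    if source.shape != candidate.shape:
        raise ValidationError(
            f"source/candidate shape mismatch: {source.shape} vs {candidate.shape}")
    rows, cols = disc.spec.grid
    s = nn.Tensor(source.transpose(2, 0, 1)[None])
    c = nn.Tensor(candidate.transpose(2, 0, 1)[None])
    with nn.no_grad():
        probs = disc(s, c).data
    return PatchScores.from_grid(probs.reshape(rows, cols))


def _scores_array(scores):
    if isinstance(scores, PatchScores):
        return scores.per_patch
    return scores  # ndarray or Tensor


def discriminator_loss(scores_real, scores_fake, mode: str = "bce"):
    """Discriminator objective over patch scores.

    bce: −mean log D(real) − mean log(1 − D(fake)).
    lsgan: ½·mean (D(real) − 1)² + ½·mean D(fake)².
    Probabilities are clamped to [ε, 1−ε] before any log.
    """
    real = _scores_array(scores_real)
    fake = _scores_array(scores_fake)
    if mode == "bce":
        real = D.clamp(real)
        fake = D.clamp(fake)
        return -1.0 * D.mean(D.log(real)) + -1.0 * D.mean(D.log(1.0 - fake))
    if mode == "lsgan":
        return 0.5 * D.mean(D.square(real - 1.0)) + 0.5 * D.mean(D.square(fake))
    raise ValidationError(f"unknown discriminator loss mode {mode!r}")
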