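"""Desk-scale experiment presets.

Full-scale training of stain translators runs for hundreds of epochs on
thousands of 1024-class tiles; nothing in that regime is checkable on a
laptop CPU in minutes.  This module fixes one small, fully seeded
configuration — 32×32 synthetic tiles, 64 training / 16 test pairs with a
uniform grade mix, a depth-2 dual-branch generator — used consistently by
the tests, the documentation examples and the reproduction script.

The learning rate here (2e-3) is deliberately larger than the full-scale
default (1e-4): a ten-epoch desk run takes only ~640 Adam steps, and total
parameter motion under Adam scales with lr × steps, so the published rate
would leave the network essentially at its initialisation.  See
docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .discriminator import PatchGridSpec
from .generator import MultiGenSpec, UNetSpec
from .image_io import DatasetSplit
from .losses import LossWeights
from .synthetic import StainSceneParams, generate_pairs
from .training import TrainConfig

UNIFORM_GRADE_MIX = (0.25, 0.25, 0.25, 0.25)


def _child_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0]
               % (2 ** 31 - 1))


def toy_scene_params(seed: int, canvas_size: int = 32,
                     noise_sd: float = 0.02, grade: int = 0) -> StainSceneParams:
    """Scene defaults scaled to a 32-px canvas (≈6 nuclei of 3–6 px)."""
    return StainSceneParams(canvas_size=canvas_size,
                            n_nuclei=max(2, round(6 * (canvas_size / 32) ** 2)),
                            nucleus_radius_range=(3.0, 6.0),
                            grade=grade, noise_sd=noise_sd, seed=seed)


def toy_dataset(seed: int, n_train: int = 64, n_test: int = 16,
                canvas_size: int = 32, grade_mix=UNIFORM_GRADE_MIX,
                noise_sd: float = 0.02) -> DatasetSplit:
    """Seeded in-memory train/test split of synthetic pairs."""
    train = generate_pairs(
        n_train, grade_mix,
        toy_scene_params(_child_seed(seed, 10), canvas_size, noise_sd),
        id_prefix="train")
    test = [] if n_test == 0 else generate_pairs(
        n_test, grade_mix,
        toy_scene_params(_child_seed(seed, 11), canvas_size, noise_sd),
        id_prefix="test")
    return DatasetSplit(train=train, test=test)


def toy_train_config(seed: int, epochs: int = 10,
                     weights: LossWeights | None = None,
                     gan_mode: str = "log") -> TrainConfig:
    """Small dual-branch configuration that trains in ~1 min on one CPU."""
    branch = UNetSpec(depth=2, base_channels=12)
    return TrainConfig(
        epochs=epochs, lr=2e-3, seed=seed, batch_size=1,
        gan_mode=gan_mode,
        weights=weights if weights is not None else LossWeights(),
        checkpoint_every=0,
        gen_spec=MultiGenSpec(fine_branch=branch, coarse_branch=branch,
                              coarse_scale_factor=2),
        disc_spec=PatchGridSpec(base_channels=12),
    )
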