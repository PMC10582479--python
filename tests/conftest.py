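import numpy as np
import pytest

import stainshift as ss


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_scene():
    """A 32-px scene with a few nuclei, light noise."""
    return ss.StainSceneParams(canvas_size=32, n_nuclei=5,
                               nucleus_radius_range=(3, 6),
                               grade=2, noise_sd=0.02, seed=7)


@pytest.fixture
def tiny_pair(tiny_scene):
    src, tgt = ss.render_pair(tiny_scene)
    return ss.ImagePair(source=src, target=tgt, id="tiny", grade=2)


def make_split(seed=5, n_train=6, n_test=2, canvas=16):
    """Very small in-memory split for fast training tests."""
    return ss.toy_dataset(seed, n_train=n_train, n_test=n_test,
                          canvas_size=canvas)


@pytest.fixture
def micro_split():
    return make_split()


def micro_config(seed=3, epochs=1, **kwargs):
    """Tiny architecture that still exercises both branches and the 4×4 grid."""
    branch = ss.UNetSpec(depth=1, base_channels=4)
    defaults = dict(
        epochs=epochs, lr=2e-3, seed=seed, checkpoint_every=0,
        gen_spec=ss.MultiGenSpec(fine_branch=branch, coarse_branch=branch),
        disc_spec=ss.PatchGridSpec(base_channels=4),
    )
    defaults.update(kwargs)
    return ss.TrainConfig(**defaults)
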