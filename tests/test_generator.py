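"""Dual-scale generator: shapes, determinism, fusion algebra, gradient flow."""

import numpy as np
import pytest

import stainshift as ss
from stainshift import nn
from stainshift.errors import ConfigurationError, ValidationError


def small_spec(depth=2, bc=6, multi=True):
    branch = ss.UNetSpec(depth=depth, base_channels=bc)
    return ss.MultiGenSpec(fine_branch=branch,
                           coarse_branch=branch if multi else None)


class TestBuild:
    def test_divisibility_accepted(self):
        ss.build_generator(ss.MultiGenSpec(
            fine_branch=ss.UNetSpec(depth=3, base_channels=4),
            coarse_branch=ss.UNetSpec(depth=3, base_channels=4),
            coarse_scale_factor=2), seed=0, image_size=64)

    def test_divisibility_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.build_generator(small_spec(depth=3), seed=0, image_size=20)

    def test_same_seed_bit_identical_parameters(self):
        a = ss.build_generator(small_spec(), seed=11)
        b = ss.build_generator(small_spec(), seed=11)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seeds_differ(self):
        a = ss.build_generator(small_spec(), seed=11)
        b = ss.build_generator(small_spec(), seed=12)
        assert any(not np.array_equal(pa.data, pb.data)
                   for pa, pb in zip(a.parameters(), b.parameters()))


class TestTranslate:
    @pytest.mark.parametrize("multi", [True, False])
    def test_output_shape_equals_input_shape(self, rng, multi):
        model = ss.build_generator(small_spec(multi=multi), seed=0)
        for size in (16, 32):
            src = rng.uniform(size=(size, size, 3))
            out = ss.translate(model, src)
            assert out.shape == src.shape

    def test_output_in_open_unit_interval(self, rng):
        model = ss.build_generator(small_spec(), seed=0)
        out = ss.translate(model, rng.uniform(size=(16, 16, 3)))
        assert out.min() > 0.0 and out.max() < 1.0

    def test_inference_deterministic(self, rng):
        model = ss.build_generator(small_spec(), seed=0)
        src = rng.uniform(size=(16, 16, 3))
        np.testing.assert_array_equal(ss.translate(model, src),
                                      ss.translate(model, src))

    def test_batch_matches_single(self, rng):
        # instance norm -> per-sample statistics -> batch equivalence
        model = ss.build_generator(small_spec(), seed=3)
        batch = rng.uniform(size=(3, 16, 16, 3))
        joint = ss.translate(model, batch)
        singles = np.stack([ss.translate(model, img) for img in batch])
        np.testing.assert_allclose(joint, singles, atol=1e-10)

    def test_out_of_range_input_rejected(self, rng):
        model = ss.build_generator(small_spec(), seed=0)
        with pytest.raises(ValidationError):
            ss.translate(model, rng.uniform(size=(16, 16, 3)) + 1.0)


class TestFusion:
    def test_shape_arithmetic(self, rng):
        model = ss.build_generator(small_spec(bc=6), seed=0)
        fine = nn.Tensor(rng.normal(size=(1, 6, 16, 16)))
        coarse = nn.Tensor(rng.normal(size=(1, 6, 16, 16)))
        out = ss.fuse_branches(model, fine, coarse)
        assert out.shape == (1, 3, 16, 16)

    def test_zero_features_give_bias_activation(self):
        model = ss.build_generator(small_spec(bc=4), seed=0)
        zf = nn.Tensor(np.zeros((1, 4, 8, 8)))
        zc = nn.Tensor(np.zeros((1, 4, 8, 8)))
        out = ss.fuse_branches(model, zf, zc).data
        expected = 1.0 / (1.0 + np.exp(-model.fusion_proj.bias.data))
        np.testing.assert_allclose(out, expected.reshape(1, 3, 1, 1) *
                                   np.ones_like(out))

    def test_permuted_concat_with_permuted_weights_identical(self, rng):
        """Algebra: swapping branch order + swapping projection weight blocks
        leaves the fused output unchanged."""
        model = ss.build_generator(small_spec(bc=4), seed=0)
        fine = nn.Tensor(rng.normal(size=(1, 4, 8, 8)))
        coarse = nn.Tensor(rng.normal(size=(1, 4, 8, 8)))
        ref = ss.fuse_branches(model, fine, coarse).data
        w = model.fusion_proj.weight.data
        model.fusion_proj.weight.data = np.concatenate(
            [w[:, 4:], w[:, :4]], axis=1)
        swapped = ss.fuse_branches(model, coarse, fine).data
        np.testing.assert_allclose(swapped, ref, atol=1e-12)

    def test_spatial_mismatch_rejected(self, rng):
        model = ss.build_generator(small_spec(bc=4), seed=0)
        with pytest.raises(ValidationError):
            ss.fuse_branches(model, nn.Tensor(rng.normal(size=(1, 4, 8, 8))),
                             nn.Tensor(rng.normal(size=(1, 4, 4, 4))))


class TestGradientFlow:
    def test_every_parameter_receives_gradient(self, rng, micro_split):
        """Both branches and the fusion head train under the full objective."""
        pair = micro_split.train[0]
        model = ss.build_generator(small_spec(depth=1, bc=4), seed=1)
        disc = ss.build_discriminator(ss.PatchGridSpec(base_channels=4), seed=1)
        x = nn.Tensor(pair.source.transpose(2, 0, 1)[None])
        y = nn.Tensor(pair.target.transpose(2, 0, 1)[None])
        fake = model(x)
        scores = disc(x, fake)
        bd = ss.total_generator_loss(scores, y, fake, ss.LossWeights())
        bd.total.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0, name

    def test_skip_connection_ablation_changes_output(self, rng):
        model = ss.build_generator(small_spec(depth=2, bc=4), seed=5)
        x = nn.Tensor(rng.uniform(size=(1, 3, 16, 16)))
        with nn.no_grad():
            normal = model(x).data
            ablated = model(x, ablate_skips=True).data
        assert not np.allclose(normal, ablated)
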