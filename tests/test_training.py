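"""Training loop: bookkeeping, determinism, checkpoint-resume, harnesses."""

import dataclasses
import math

import numpy as np
import pytest

import stainshift as ss
from stainshift import nn
from stainshift.errors import ParameterError
from stainshift.training import Trainer, build_models

from conftest import make_split, micro_config


def history_totals(state):
    return [(h["total"], h["d_loss"]) for h in state.loss_history]


class TestStepBookkeeping:
    def test_one_epoch_four_pairs_four_steps(self):
        split = make_split(n_train=4, n_test=2)
        _, state, _ = ss.fit(split, micro_config(epochs=1))
        assert state.step == 4
        assert state.epoch == 1
        assert len(state.loss_history) == 4

    def test_l1_term_finite_and_recorded(self):
        split = make_split(n_train=2, n_test=0)
        _, state, _ = ss.fit(split, micro_config(epochs=1))
        assert all(math.isfinite(h["l1"]) and h["l1"] >= 0
                   for h in state.loss_history)

    def test_frozen_uninformative_discriminator_gives_ln2(self, micro_split):
        """With all D outputs at 0.5 and λ1=λ2=0 the generator loss is ln 2."""
        cfg = micro_config(weights=ss.LossWeights(lambda1=0, lambda2=0))
        models = build_models(cfg, 16)
        for p in models.discriminator.parameters():
            p.data = np.zeros_like(p.data)  # logits 0 -> sigmoid 0.5
        pair = micro_split.train[0]
        x = nn.Tensor(pair.source.transpose(2, 0, 1)[None])
        fake = models.generator(x)
        scores = models.discriminator(x, fake)
        np.testing.assert_allclose(scores.data, 0.5)
        bd = ss.total_generator_loss(scores, nn.Tensor(x.data), fake, cfg.weights)
        assert bd.as_floats().total == pytest.approx(math.log(2), abs=1e-12)

    def test_invalid_config_rejected_before_compute(self):
        with pytest.raises(ParameterError):
            ss.TrainConfig(epochs=0)
        with pytest.raises(ParameterError):
            ss.TrainConfig(lr=-1.0)
        with pytest.raises(ParameterError):
            ss.TrainConfig(gan_mode="wasserstein")


class TestDeterminism:
    def test_identical_runs_identical_histories_and_metrics(self):
        results = []
        for _ in range(2):
            split = make_split(seed=8)
            models, state, report = ss.fit(split, micro_config(seed=4, epochs=2))
            results.append((history_totals(state),
                            report.mean_psnr, report.mean_ssim))
        assert results[0] == results[1]

    def test_checkpoint_resume_matches_uninterrupted(self, tmp_path):
        split = make_split(seed=8)
        cfg = micro_config(seed=4, epochs=4, checkpoint_every=2)
        _, full_state, full_report = ss.fit(split, cfg, out_dir=tmp_path / "full")
        # resume from the epoch-2 checkpoint of the same run
        _, res_state, res_report = ss.fit(
            split, cfg, resume_from=tmp_path / "full" / "ckpt_epoch2")
        assert res_state.epoch == 4
        assert history_totals(res_state) == history_totals(full_state)
        assert res_report.mean_psnr == full_report.mean_psnr
        assert res_report.mean_ssim == full_report.mean_ssim

    def test_checkpoint_roundtrip_preserves_translation(self, tmp_path):
        split = make_split(seed=2, n_train=2, n_test=0)
        cfg = micro_config(seed=1, epochs=1)
        models = build_models(cfg, 16)
        trainer = Trainer(models, cfg)
        trainer.step(split.train[:1])
        ss.save_checkpoint(tmp_path / "ck", trainer)
        loaded_models, _ = ss.load_checkpoint(tmp_path / "ck")
        src = split.train[0].source
        np.testing.assert_array_equal(ss.translate(models.generator, src),
                                      ss.translate(loaded_models.generator, src))

    def test_missing_checkpoint_raises_io(self, tmp_path):
        with pytest.raises(IOError):
            ss.load_checkpoint(tmp_path / "nope")


class TestAblationHarness:
    def test_variant_configs_differ_only_in_documented_fields(self):
        base = micro_config()
        ggan = ss.variant_config(base, "ggan")
        dgan = ss.variant_config(base, "dgan")
        star = ss.variant_config(base, "mggan_star")
        full = ss.variant_config(base, "mggan")
        # ggan: single branch + no cross term
        assert ggan.gen_spec.coarse_branch is None
        assert ggan.weights.lambda2 == 0
        assert dataclasses.replace(
            ggan, gen_spec=base.gen_spec, weights=base.weights) == base
        # dgan / mggan_star: dual branch, no cross term — same structure
        assert star == dgan
        assert dataclasses.replace(dgan, weights=base.weights) == base
        # mggan: the base itself
        assert full == base

    def test_unknown_variant_rejected(self):
        with pytest.raises(ParameterError):
            ss.variant_config(micro_config(), "cyclegan")

    def test_single_variant_runs(self):
        split = make_split(n_train=4, n_test=2)
        reports = ss.run_ablation(split, micro_config(epochs=1),
                                  variants=("mggan",))
        assert set(reports) == {"mggan"}
        assert reports["mggan"].n_images == 2


class TestSweepHarness:
    def test_1x1_grid_matches_direct_fit(self):
        split = make_split(n_train=4, n_test=2)
        cfg = micro_config(epochs=1)
        grid = ss.sweep_lambdas(split, cfg, [100.0], [10.0])
        _, _, direct = ss.fit(make_split(n_train=4, n_test=2), cfg)
        report = grid[(100.0, 10.0)]
        assert report.per_image == direct.per_image

    def test_grid_bookkeeping(self):
        split = make_split(n_train=2, n_test=2)
        grid = ss.sweep_lambdas(split, micro_config(epochs=1),
                                [80, 100, 120], [0.1, 10, 100])
        assert len(grid) == 9
        assert (100, 10) in grid  # the default operating point is on the grid

    def test_negative_lambda_rejected(self, micro_split):
        with pytest.raises(ParameterError):
            ss.sweep_lambdas(micro_split, micro_config(), [-1], [10])
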