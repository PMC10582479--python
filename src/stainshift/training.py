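"""Alternating adversarial training of the translator.

Each step performs one discriminator update (real pair against a detached
fake) followed by one generator update with the composite objective.  Both
networks use Adam with β1 = 0.5, β2 = 0.999 and a fixed learning rate
(default 1e-4, the published operating point for full-scale training; the
desk-scale experiments in the docs use a larger rate, see docs/methods.md).
Runs are reproducible: data order, parameter init and every other random
draw derive from the config seed, and checkpoints carry enough state
(parameters, Adam moments, RNG state) for bit-identical resumption.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .discriminator import (PatchGridSpec, build_discriminator,
                            discriminator_loss)
from .errors import ParameterError
from .generator import MultiGenSpec, UNetSpec, build_generator, validate_spec
from .image_io import DatasetSplit
from .losses import LossWeights, total_generator_loss
from .metrics import MetricReport, SSIMConfig, evaluate_dataset

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    seed: int = 0
    gan_mode: str = "log"            # "log" (BCE discriminator) or "lsgan"
    weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_every: int = 50
    ce_reference: str = "target"     # "target" or "source"
    gen_spec: MultiGenSpec = field(default_factory=MultiGenSpec)
    disc_spec: PatchGridSpec = field(default_factory=PatchGridSpec)

    def __post_init__(self):
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.lr <= 0:
            raise ParameterError("lr must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ParameterError("betas must lie in [0, 1)")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.gan_mode not in ("log", "lsgan"):
            raise ParameterError(f"unknown gan_mode {self.gan_mode!r}")
        if self.ce_reference not in ("target", "source"):
            raise ParameterError("ce_reference must be 'target' or 'source'")

    @property
    def d_mode(self) -> str:
        return "bce" if self.gan_mode == "log" else "lsgan"


@dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    loss_history: list = field(default_factory=list)


@dataclass
class Models:
    generator: object
    discriminator: object


def _stack(pairs):
    x = np.stack([p.source.transpose(2, 0, 1) for p in pairs])
    y = np.stack([p.target.transpose(2, 0, 1) for p in pairs])
    return x, y


class Trainer:
    def __init__(self, models: Models, config: TrainConfig):
        self.models = models
        self.config = config
        self.g_opt = nn.Adam(models.generator.parameters(),
                             lr=config.lr, beta1=config.beta1, beta2=config.beta2)
        self.d_opt = nn.Adam(models.discriminator.parameters(),
                             lr=config.lr, beta1=config.beta1, beta2=config.beta2)
        self.rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(2,)))
        self.state = TrainState()

    def step(self, pair_batch):
        """One D update then one G update on a batch of ImagePairs."""
        cfg = self.config
        x_np, y_np = _stack(pair_batch)
        x, y = nn.Tensor(x_np), nn.Tensor(y_np)

        # discriminator: real pair vs detached fake
        with nn.no_grad():
            fake_detached = self.models.generator(x).data
        self.d_opt.zero_grad()
        d_real = self.models.discriminator(x, y)
        d_fake = self.models.discriminator(x, nn.Tensor(fake_detached))
        d_loss = discriminator_loss(d_real, d_fake, cfg.d_mode)
        d_loss.backward()
        self.d_opt.step()

        # generator: adversarial + L1 + cross-entropy consistency
        self.g_opt.zero_grad()
        self.d_opt.zero_grad()
        fake = self.models.generator(x)
        scores_fake = self.models.discriminator(x, fake)
        ce_ref = y if cfg.ce_reference == "target" else x
        breakdown = total_generator_loss(scores_fake, y, fake,
                                         weights=cfg.weights, mode=cfg.gan_mode,
                                         ce_reference=ce_ref)
        breakdown.total.backward()
        self.g_opt.step()

        scalars = breakdown.as_floats()
        d_val = d_loss.item()
        values = (scalars.adv, scalars.l1, scalars.cross, scalars.total, d_val)
        if not all(np.isfinite(v) for v in values):
            raise RuntimeError(
                f"non-finite loss at step {self.state.step}: "
                f"adv={scalars.adv} l1={scalars.l1} cross={scalars.cross} "
                f"d={d_val}")
        self.state.step += 1
        self.state.loss_history.append({
            "step": self.state.step, "epoch": self.state.epoch + 1,
            "adv": scalars.adv, "l1": scalars.l1, "cross": scalars.cross,
            "total": scalars.total, "d_loss": d_val,
        })
        return scalars, d_val


def train_step(trainer: Trainer, pair_batch):
    """Functional wrapper: returns (models, generator LossBreakdown, d_loss)."""
    breakdown, d_loss = trainer.step(pair_batch)
    return trainer.models, breakdown, d_loss


def build_models(config: TrainConfig, image_size: int) -> Models:
    validate_spec(config.gen_spec, image_size)
    gen = build_generator(config.gen_spec, config.seed, image_size=image_size)
    disc = build_discriminator(config.disc_spec, config.seed)
    return Models(generator=gen, discriminator=disc)


def fit(dataset: DatasetSplit, config: TrainConfig, out_dir=None,
        resume_from=None, ssim_config: SSIMConfig | None = None):
    """Train on ``dataset.train``; evaluate on ``dataset.test`` when present.

    Returns (models, state, report-or-None).  With ``out_dir`` set,
    checkpoints land in ``out_dir/ckpt_epoch{N}`` every
    ``checkpoint_every`` epochs and at the end.
    """
    if not dataset.train:
        raise ParameterError("training split is empty")
    image_size = dataset.train[0].source.shape[0]

    if resume_from is not None:
        models, trainer = load_checkpoint(resume_from)
        config = trainer.config
    else:
        models = build_models(config, image_size)
        trainer = Trainer(models, config)

    n = len(dataset.train)
    while trainer.state.epoch < config.epochs:
        order = trainer.rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = [dataset.train[i] for i in order[start:start + config.batch_size]]
            trainer.step(batch)
        trainer.state.epoch += 1
        if out_dir and config.checkpoint_every > 0 and (
                trainer.state.epoch % config.checkpoint_every == 0
                or trainer.state.epoch == config.epochs):
            save_checkpoint(
                os.path.join(out_dir, f"ckpt_epoch{trainer.state.epoch}"), trainer)

    report = None
    if dataset.test:
        report = evaluate_dataset(dataset.test, models.generator,
                                  ssim_config=ssim_config)
    return models, trainer.state, report


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _config_to_dict(config: TrainConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.gen_spec.coarse_branch is None:
        d["gen_spec"]["coarse_branch"] = None
    return d


def config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    gs = dict(d["gen_spec"])
    gs["fine_branch"] = UNetSpec(**gs["fine_branch"])
    if gs["coarse_branch"] is not None:
        gs["coarse_branch"] = UNetSpec(**gs["coarse_branch"])
    d["gen_spec"] = MultiGenSpec(**gs)
    ds = dict(d["disc_spec"])
    ds["grid"] = tuple(ds["grid"])
    d["disc_spec"] = PatchGridSpec(**ds)
    d["weights"] = LossWeights(**d["weights"])
    return TrainConfig(**d)


def save_checkpoint(path, trainer: Trainer):
    os.makedirs(path, exist_ok=True)
    arrays = {}
    for name, p in trainer.models.generator.named_parameters():
        arrays[f"g::{name}"] = p.data
    for name, p in trainer.models.discriminator.named_parameters():
        arrays[f"d::{name}"] = p.data
    for tag, opt in (("gopt", trainer.g_opt), ("dopt", trainer.d_opt)):
        st = opt.state_dict()
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"{tag}::m{i}"] = m
            arrays[f"{tag}::v{i}"] = v
    np.savez(os.path.join(path, "weights.npz"), **arrays)
    meta = {
        "format": "stainshift-checkpoint",
        "version": CHECKPOINT_VERSION,
        "epoch": trainer.state.epoch,
        "step": trainer.state.step,
        "gopt_t": trainer.g_opt.t,
        "dopt_t": trainer.d_opt.t,
        "config": _config_to_dict(trainer.config),
        "rng_state": trainer.rng.bit_generator.state,
        "loss_history": trainer.state.loss_history,
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh)


def load_checkpoint(path):
    """Rebuild models + trainer exactly as saved (bit-identical resume)."""
    meta_path = os.path.join(path, "meta.json")
    if not os.path.exists(meta_path):
        raise IOError(f"no checkpoint at {path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format") != "stainshift-checkpoint":
        raise IOError(f"{path} is not a stainshift checkpoint")
    if meta["version"] > CHECKPOINT_VERSION:
        raise IOError(f"checkpoint version {meta['version']} is too new")
    config = config_from_dict(meta["config"])
    gen = build_generator(config.gen_spec, config.seed)
    disc = build_discriminator(config.disc_spec, config.seed)
    models = Models(generator=gen, discriminator=disc)
    trainer = Trainer(models, config)

    with np.load(os.path.join(path, "weights.npz")) as npz:
        gen.load_state_dict({k[3:]: npz[k] for k in npz.files
                             if k.startswith("g::")})
        disc.load_state_dict({k[3:]: npz[k] for k in npz.files
                              if k.startswith("d::")})
        for tag, opt in (("gopt", trainer.g_opt), ("dopt", trainer.d_opt)):
            m = [npz[f"{tag}::m{i}"] for i in range(len(opt.params))]
            v = [npz[f"{tag}::v{i}"] for i in range(len(opt.params))]
            opt.load_state_dict({"t": meta[f"{tag[0]}opt_t"], "m": m, "v": v})
    trainer.rng.bit_generator.state = meta["rng_state"]
    trainer.state = TrainState(epoch=meta["epoch"], step=meta["step"],
                               loss_history=list(meta["loss_history"]))
    return models, trainer


# ---------------------------------------------------------------------------
# ablation and hyper-parameter harnesses
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = ("ggan", "dgan", "mggan_star", "mggan")


def variant_config(base: TrainConfig, variant: str) -> TrainConfig:
    """Ablation variants of the full model.

    ggan: single (fine) generator branch, patch discriminator, no
    cross-entropy term.  dgan: dual-branch generator, patch discriminator,
    no cross-entropy term.  mggan_star: the full architecture with the
    cross-entropy term removed — structurally identical to dgan, kept as a
    separately named row of the harness.  mggan: the full model.
    """
    v = variant.lower()
    if v not in ABLATION_VARIANTS:
        raise ParameterError(
            f"unknown variant {variant!r}; expected one of {ABLATION_VARIANTS}")
    no_cross = LossWeights(lambda1=base.weights.lambda1, lambda2=0.0)
    if v == "ggan":
        gen_spec = dataclasses.replace(base.gen_spec, coarse_branch=None)
        return dataclasses.replace(base, gen_spec=gen_spec, weights=no_cross)
    if v in ("dgan", "mggan_star"):
        return dataclasses.replace(base, weights=no_cross)
    return base


def run_ablation(dataset: DatasetSplit, base_config: TrainConfig,
                 variants=ABLATION_VARIANTS,
                 ssim_config: SSIMConfig | None = None) -> dict:
    """Train each variant with shared seeds; one MetricReport per variant."""
    if not dataset.test:
        raise ParameterError("ablation needs a test split to report on")
    out = {}
    for variant in variants:
        cfg = variant_config(base_config, variant)
        _, _, report = fit(dataset, cfg, ssim_config=ssim_config)
        out[variant.lower()] = report
    return out


def sweep_lambdas(dataset: DatasetSplit, config: TrainConfig,
                  lambda1_values, lambda2_values,
                  ssim_config: SSIMConfig | None = None) -> dict:
    """Grid of (λ1, λ2) fits with shared seeds -> {(λ1, λ2): MetricReport}."""
    lambda1_values = list(lambda1_values)
    lambda2_values = list(lambda2_values)
    if not lambda1_values or not lambda2_values:
        raise ParameterError("lambda value lists must be nonempty")
    if any(v < 0 for v in lambda1_values + lambda2_values):
        raise ParameterError("lambda values must be nonnegative")
    if not dataset.test:
        raise ParameterError("sweep needs a test split to report on")
    grid = {}
    for l1 in lambda1_values:
        for l2 in lambda2_values:
            cfg = dataclasses.replace(
                config, weights=LossWeights(lambda1=l1, lambda2=l2))
            _, _, report = fit(dataset, cfg, ssim_config=ssim_config)
            grid[(l1, l2)] = report
    return grid
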