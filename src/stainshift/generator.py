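"""Dual-scale U-shaped generator for paired stain translation.

The generator runs two independent U-Net branches: a *fine* branch on the
input image and a *coarse* branch on the input downsampled by an integer
scale factor (default 2).  The coarse branch sees a larger effective
receptive field (low-frequency tissue layout); the fine branch preserves
high-frequency detail.  Both branches emit full-resolution feature maps
(the coarse one is upsampled back with nearest-neighbour interpolation),
which are concatenated and projected by a learned 1×1 convolution to three
channels, squashed into the open interval (0, 1) by a sigmoid.

Single-branch operation (fine branch only) is supported for ablations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError

_OUT_EPS = 1e-7  # keeps translate() outputs strictly inside (0, 1)


@dataclass(frozen=True)
class UNetSpec:
    depth: int = 3
    base_channels: int = 32
    use_residual_blocks: bool = True
    norm_mode: str = "instance"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.norm_mode not in ("instance", "batch", "none"):
            raise ConfigurationError(f"unknown norm_mode {self.norm_mode!r}")


@dataclass(frozen=True)
class MultiGenSpec:
    fine_branch: UNetSpec = UNetSpec()
    coarse_branch: UNetSpec | None = UNetSpec()
    coarse_scale_factor: int = 2
    fusion: str = "concat_project"

    def __post_init__(self):
        if self.coarse_scale_factor < 2:
            raise ConfigurationError("coarse_scale_factor must be >= 2")
        if self.fusion != "concat_project":
            raise ConfigurationError(f"unknown fusion mode {self.fusion!r}")

    @property
    def multi(self) -> bool:
        return self.coarse_branch is not None


def validate_spec(spec: MultiGenSpec, image_size: int):
    """Image size must survive every downsampling stage exactly."""
    need = 2 ** spec.fine_branch.depth
    if image_size % need:
        raise ConfigurationError(
            f"image size {image_size} not divisible by 2^depth = {need}")
    if spec.multi:
        need = 2 ** spec.coarse_branch.depth * spec.coarse_scale_factor
        if image_size % need:
            raise ConfigurationError(
                f"image size {image_size} not divisible by "
                f"2^depth * scale_factor = {need} (coarse branch)")


def _channels(base: int, level: int) -> int:
    # double per level, capped at 4x base to bound desk-scale cost
    return base * min(2 ** level, 4)


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, norm, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, rng)
        self.norm = nn.Norm(cout, norm)

    def forward(self, x):
        return nn.leaky_relu(self.norm(self.conv(x)), 0.2)


class _ResBlock(nn.Module):
    """Two 3×3 convs with an additive (1×1-projected) shortcut."""

    def __init__(self, cin, cout, norm, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.norm1 = nn.Norm(cout, norm)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.norm2 = nn.Norm(cout, norm)
        self.proj = nn.Conv2d(cin, cout, 1, rng) if cin != cout else None

    def forward(self, x):
        y = nn.leaky_relu(self.norm1(self.conv1(x)), 0.2)
        y = self.norm2(self.conv2(y))
        shortcut = self.proj(x) if self.proj is not None else x
        return nn.leaky_relu(y + shortcut, 0.2)


class UNetBranch(nn.Module):
    """Encoder–decoder with skip connections; emits a feature map, not RGB."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator, in_channels=3):
        super().__init__()
        self.spec = spec
        block = _ResBlock if spec.use_residual_blocks else _ConvBlock
        bc, d, norm = spec.base_channels, spec.depth, spec.norm_mode
        self.inc = block(in_channels, bc, norm, rng)
        for i in range(1, d + 1):
            cin, cout = _channels(bc, i - 1), _channels(bc, i)
            setattr(self, f"down{i}", nn.Conv2d(cin, cout, 3, rng, stride=2))
            setattr(self, f"enc{i}", block(cout, cout, norm, rng))
        for i in range(d, 0, -1):
            cin, cout = _channels(bc, i), _channels(bc, i - 1)
            setattr(self, f"up{i}", nn.Conv2d(cin, cout, 3, rng))
            setattr(self, f"dec{i}", block(2 * cout, cout, norm, rng))

    def forward(self, x, ablate_skips: bool = False):
        d = self.spec.depth
        h = x.shape[2] if isinstance(x, nn.Tensor) else x.shape[2]
        if h % (2 ** d):
            raise ConfigurationError(
                f"input size {h} not divisible by 2^depth = {2 ** d}")
        skips = []
        h = self.inc(x)
        for i in range(1, d + 1):
            skips.append(h)
            h = nn.leaky_relu(getattr(self, f"down{i}")(h), 0.2)
            h = getattr(self, f"enc{i}")(h)
        for i in range(d, 0, -1):
            h = getattr(self, f"up{i}")(nn.upsample_nearest(h, 2))
            skip = skips[i - 1]
            if ablate_skips:
                skip = nn.Tensor(np.zeros_like(skip.data))
            h = getattr(self, f"dec{i}")(nn.concat([h, skip], axis=1))
        return h


class MultiGenerator(nn.Module):
    """Fine + optional coarse U-Net branch with concat-project fusion."""

    def __init__(self, spec: MultiGenSpec, seed: int):
        super().__init__()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
        self.fine = UNetBranch(spec.fine_branch, rng)
        fusion_in = spec.fine_branch.base_channels
        if spec.multi:
            self.coarse = UNetBranch(spec.coarse_branch, rng)
            fusion_in += spec.coarse_branch.base_channels
        else:
            self.coarse = None
        self.fusion_proj = nn.Conv2d(fusion_in, 3, 1, rng)

    def fuse_branches(self, fine_out, coarse_out=None):
        """Concatenate branch feature maps, 1×1-project to RGB, sigmoid."""
        if coarse_out is not None:
            if coarse_out.shape[2:] != fine_out.shape[2:]:
                raise ValidationError(
                    f"fusion spatial mismatch: {fine_out.shape} vs {coarse_out.shape}")
            feat = nn.concat([fine_out, coarse_out], axis=1)
        else:
            feat = fine_out
        return nn.sigmoid(self.fusion_proj(feat))

    def forward(self, x, ablate_skips: bool = False):
        x = nn.as_tensor(x)
        fine_feat = self.fine(x, ablate_skips=ablate_skips)
        coarse_feat = None
        if self.coarse is not None:
            f = self.spec.coarse_scale_factor
            if x.shape[2] % f or x.shape[3] % f:
                raise ConfigurationError(
                    f"input {x.shape[2]}x{x.shape[3]} not divisible by "
                    f"coarse_scale_factor {f}")
            xc = nn.avg_pool2d(x, f)
            coarse_feat = nn.upsample_nearest(self.coarse(xc), f)
        return self.fuse_branches(fine_feat, coarse_feat)


def build_generator(spec: MultiGenSpec, seed: int,
                    image_size: int | None = None) -> MultiGenerator:
    """Construct a generator; parameter init is deterministic under seed."""
    if image_size is not None:
        validate_spec(spec, image_size)
    return MultiGenerator(spec, seed)


def fuse_branches(model: MultiGenerator, fine_out, coarse_out=None):
    return model.fuse_branches(fine_out, coarse_out)


def _to_nchw(source: np.ndarray) -> np.ndarray:
    if source.ndim == 3:
        return source.transpose(2, 0, 1)[None]
    if source.ndim == 4:
        return source.transpose(0, 3, 1, 2)
    raise ValidationError(f"expected H×W×3 or N×H×W×3, got shape {source.shape}")


def translate(model: MultiGenerator, source: np.ndarray) -> np.ndarray:
    """Map a source image (or batch) to its translated image, values in (0,1)."""
    source = np.asarray(source, dtype=np.float64)
    if source.min() < 0.0 or source.max() > 1.0:
        raise ValidationError("source values must lie in [0, 1]")
    single = source.ndim == 3
    x = _to_nchw(source)
    if x.shape[1] != 3:
        raise ValidationError("source must have 3 channels")
    with nn.no_grad():
        out = model(nn.Tensor(x)).data
    out = np.clip(out, _OUT_EPS, 1.0 - _OUT_EPS)
    out = out.transpose(0, 2, 3, 1)
    return out[0] if single else out
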