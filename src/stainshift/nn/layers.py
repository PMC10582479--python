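"""Parameterised layers on top of the autodiff engine.

Modules hold :class:`Tensor` parameters (registered automatically via
attribute assignment) and expose ``parameters()`` / ``state_dict()`` /
``load_state_dict()`` for optimisation and checkpointing.  Initialisation
is deterministic: every layer draws its weights from the
``numpy.random.Generator`` passed to its constructor.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mname}.")

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3×3-style convolution with He-normal init (deterministic per rng)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride = stride
        self.padding = padding
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class Norm(Module):
    """Feature normalisation with learned per-channel affine.

    mode "instance": statistics over (H, W) for each sample and channel —
    batch-size independent, the usual choice for image translation.
    mode "batch": statistics over (N, H, W) per channel, computed from the
    current batch (no running averages are kept).
    mode "none": identity.
    """

    def __init__(self, channels: int, mode: str = "instance", eps: float = 1e-5):
        super().__init__()
        if mode not in ("instance", "batch", "none"):
            raise ValueError(f"unknown norm mode {mode!r}")
        self.mode = mode
        self.eps = eps
        if mode != "none":
            self.gain = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
            self.shift = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def forward(self, x):
        if self.mode == "none":
            return x
        axes = (2, 3) if self.mode == "instance" else (0, 2, 3)
        mu = T.tmean(x, axis=axes, keepdims=True)
        centered = x - mu
        var = T.tmean(centered * centered, axis=axes, keepdims=True)
        normed = centered * T.power(var + self.eps, -0.5)
        return normed * self.gain + self.shift


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return T.leaky_relu(x, self.slope)
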