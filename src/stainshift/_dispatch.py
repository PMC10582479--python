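"""Tiny numeric shims that work on both ndarrays and autodiff Tensors.

Loss formulas are written once against these helpers and can therefore be
evaluated on plain arrays (reporting, oracle tests) or inside the autodiff
graph (training) without duplication.
"""

from __future__ import annotations

import numpy as np

from . import nn

#: probability clamp applied before any logarithm
EPS = 1e-7


def is_tensor(x) -> bool:
    return isinstance(x, nn.Tensor)


def log(x):
    return nn.log(x) if is_tensor(x) else np.log(x)


def mean(x):
    return nn.tmean(x) if is_tensor(x) else float(np.mean(x))


def clamp(x, lo: float = EPS, hi: float = 1.0 - EPS):
    return nn.clamp(x, lo, hi) if is_tensor(x) else np.clip(x, lo, hi)


def absolute(x):
    return nn.absolute(x) if is_tensor(x) else np.abs(x)


def square(x):
    return nn.power(x, 2) if is_tensor(x) else np.square(x)


def to_float(x) -> float:
    """Collapse a scalar result to a Python float (Tensor or numpy)."""
    return x.item() if is_tensor(x) else float(x)
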