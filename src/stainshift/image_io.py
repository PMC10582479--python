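"""Paired-image I/O, intensity normalisation and dataset splits.

All in-memory images are H×W×3 float arrays on the [0, 1] scale (8- or
16-bit files are divided by their bit-depth maximum on load and quantised
by ``round(v * (2^bits - 1))`` on save).  Two on-disk dialects are
supported: parallel ``A/`` (source) and ``B/`` (target) directory trees,
and single side-by-side composites with the source on the left half.
"""

from __future__ import annotations

import csv
import glob
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, ParameterError, ValidationError

DIALECTS = ("paired_dirs", "side_by_side")


@dataclass
class ImagePair:
    """A registered (source, target) RGB pair, optionally grade-labelled."""

    source: np.ndarray
    target: np.ndarray
    id: str = ""
    grade: int | None = None

    def __post_init__(self):
        for name, img in (("source", self.source), ("target", self.target)):
            if img.ndim != 3 or img.shape[2] != 3:
                raise ValidationError(f"{name} must be H×W×3, got {img.shape}")
            if img.min() < 0.0 or img.max() > 1.0:
                raise ValidationError(f"{name} values must lie in [0, 1]")
        if self.source.shape != self.target.shape:
            raise FormatError(
                f"source/target shape mismatch: {self.source.shape} vs {self.target.shape}")


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    test: list = field(default_factory=list)


def _read_raw(path) -> np.ndarray:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such image: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise FormatError(f"{path}: unsupported dtype {arr.dtype} (need uint8/uint16)")


def load_image(path) -> np.ndarray:
    """Read one PNG/TIFF into a [0, 1] float array."""
    return _read_raw(path)


def save_image(image: np.ndarray, path, bit_depth: int = 8):
    """Quantise to ``round(v * (2^bits - 1))`` and write losslessly.

    PNG supports 8-bit output; 16-bit output requires TIFF.  Values must
    already lie in [0, 1] — callers clip explicitly.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValidationError("save_image requires values in [0, 1]; clip first")
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if bit_depth == 8:
        q = np.rint(image * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        if ext not in (".tif", ".tiff"):
            raise FormatError("16-bit output is only supported for TIFF files")
        q = np.rint(image * 65535.0).astype(np.uint16)
    else:
        raise ParameterError("bit_depth must be 8 or 16")
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    else:
        iio.imwrite(path, q)


def split_side_by_side(image: np.ndarray):
    """Split a composite at the exact horizontal midpoint."""
    w = image.shape[1]
    if w % 2:
        raise FormatError(f"side_by_side image width {w} is odd")
    return image[:, : w // 2], image[:, w // 2:]


def load_pair(path_or_paths, dialect: str = "paired_dirs",
              pair_id: str = "", grade: int | None = None) -> ImagePair:
    """Load one pair: (source_path, target_path) or a single composite path."""
    if dialect == "paired_dirs":
        src_path, tgt_path = path_or_paths
        src, tgt = _read_raw(src_path), _read_raw(tgt_path)
    elif dialect == "side_by_side":
        src, tgt = split_side_by_side(_read_raw(path_or_paths))
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    if not pair_id:
        p = path_or_paths[0] if dialect == "paired_dirs" else path_or_paths
        pair_id = os.path.splitext(os.path.basename(os.fspath(p)))[0]
    return ImagePair(source=src, target=tgt, id=pair_id, grade=grade)


def load_dataset(root, dialect: str = "paired_dirs") -> list:
    """Load every pair under ``root``, using the manifest for grades if present."""
    root = os.fspath(root)
    grades = {}
    manifest = os.path.join(root, "manifest.csv")
    if os.path.exists(manifest):
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                grades[row["name"]] = int(row["grade"])
    pairs = []
    if dialect == "paired_dirs":
        a_dir = os.path.join(root, "A")
        if not os.path.isdir(a_dir):
            raise IOError(f"{root} has no A/ directory (dialect paired_dirs)")
        for pa in sorted(glob.glob(os.path.join(a_dir, "*.png")) +
                         glob.glob(os.path.join(a_dir, "*.tif*"))):
            name = os.path.splitext(os.path.basename(pa))[0]
            pb = os.path.join(root, "B", os.path.basename(pa))
            pairs.append(load_pair((pa, pb), "paired_dirs",
                                   pair_id=name, grade=grades.get(name)))
    elif dialect == "side_by_side":
        for p in sorted(glob.glob(os.path.join(root, "*.png")) +
                        glob.glob(os.path.join(root, "*.tif*"))):
            name = os.path.splitext(os.path.basename(p))[0]
            pairs.append(load_pair(p, "side_by_side",
                                   pair_id=name, grade=grades.get(name)))
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    if not pairs:
        raise IOError(f"no image pairs found under {root}")
    return pairs


def split_dataset(pairs, test_fraction: float, seed: int) -> DatasetSplit:
    """Deterministic shuffled split; test size is ``round(n * fraction)``."""
    n = len(pairs)
    if n < 2:
        raise ParameterError("need at least 2 pairs to split")
    if not (0.0 < test_fraction < 1.0):
        raise ParameterError("test_fraction must lie strictly between 0 and 1")
    order = np.random.default_rng(seed).permutation(n)
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    test_idx = set(order[:n_test].tolist())
    split = DatasetSplit()
    for i in range(n):
        (split.test if i in test_idx else split.train).append(pairs[i])
    return split
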