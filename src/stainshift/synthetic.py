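"""Procedural paired stain-image generator.

Emulates registered HE/IHC tile pairs at desk scale: a scene is a set of
elliptical nuclei on a uniform background.  The source rendering mimics an
HE appearance (pale eosin background, dark hematoxylin nuclei); the target
rendering keeps the identical geometry but recolours it as an IHC tile with
a DAB-brown membrane ring around each nucleus whose intensity grows with an
integer expression grade in {0, 1, 2, 3} — grade 0 shows no membrane
staining at all, grade 3 the full stain colour.  This mirrors how HER2
expression categories are defined by membrane-staining completeness and
intensity, and gives a known deterministic source→target mapping so that
translation models can be trained and scored without any external data.

Everything is a pure function of ``StainSceneParams``: the layout, both
renders and the additive Gaussian pixel noise each draw from independent
child streams of the scene seed, so a dataset is byte-reproducible from its
base seed alone.
"""

from __future__ import annotations

import csv
import dataclasses
import os
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

# Fixed colour anchors on the [0, 1] RGB scale.  These are configuration
# constants, not fitted values: keeping them fixed keeps the ground-truth
# source->target mapping exactly known for oracle checks.
HE_BACKGROUND = np.array([0.91, 0.79, 0.87])   # pale eosin
HE_NUCLEUS = np.array([0.27, 0.18, 0.46])      # hematoxylin
IHC_BACKGROUND = np.array([0.95, 0.93, 0.90])  # unstained tissue
IHC_NUCLEUS = np.array([0.52, 0.55, 0.76])     # haematoxylin counterstain
DAB_BROWN = np.array([0.40, 0.25, 0.12])       # membrane stain (full strength)

#: membrane ring outer boundary, as a multiple of the nucleus radii
RING_SCALE = 1.45

GRADES = (0, 1, 2, 3)


@dataclass(frozen=True)
class StainSceneParams:
    """Parameters of one synthetic scene (and, via spawned seeds, a dataset)."""

    canvas_size: int = 64
    n_nuclei: int = 12
    nucleus_radius_range: tuple = (4.0, 9.0)
    grade: int = 1
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.canvas_size < 16:
            raise ParameterError("canvas_size must be >= 16")
        if self.n_nuclei < 0:
            raise ParameterError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ParameterError("nucleus_radius_range must satisfy 0 < min <= max")
        if self.grade not in GRADES:
            raise ParameterError(f"grade must be one of {GRADES}")
        if not (0 <= self.noise_sd < 0.5):
            raise ParameterError("noise_sd must lie in [0, 0.5)")


@dataclass(frozen=True)
class SceneLayout:
    """Ellipse nuclei as (center_x, center_y, radius_x, radius_y, angle) rows."""

    nuclei: tuple  # tuple of 5-tuples, pixel units / radians


def _streams(params: StainSceneParams):
    """Independent child RNGs for layout, source noise, target noise."""
    children = np.random.SeedSequence(params.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def sample_layout(params: StainSceneParams) -> SceneLayout:
    """Draw nucleus positions, radii and orientations for one scene.

    Centres are placed so that the full ellipse (but not necessarily its
    membrane ring) lies inside the canvas; deterministic given the seed.
    """
    rng, _, _ = _streams(params)
    lo, hi = params.nucleus_radius_range
    s = params.canvas_size
    nuclei = []
    for _ in range(params.n_nuclei):
        rx = rng.uniform(lo, hi)
        ry = rng.uniform(lo, hi)
        margin = max(rx, ry)
        cx = rng.uniform(margin, s - margin)
        cy = rng.uniform(margin, s - margin)
        angle = rng.uniform(0.0, np.pi)
        nuclei.append((cx, cy, rx, ry, angle))
    return SceneLayout(nuclei=tuple(nuclei))


def _ellipse_quadform(layout: SceneLayout, size: int) -> np.ndarray:
    """Per-nucleus quadratic form q(x,y); q<=1 is the nucleus interior.

    Returns an array (n_nuclei, H, W); for an empty layout, (0, H, W).
    """
    yy, xx = np.mgrid[0:size, 0:size]
    xx = xx + 0.5  # pixel-centre addressing
    yy = yy + 0.5
    qs = []
    for cx, cy, rx, ry, ang in layout.nuclei:
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(ang) + dy * np.sin(ang)
        v = -dx * np.sin(ang) + dy * np.cos(ang)
        qs.append((u / rx) ** 2 + (v / ry) ** 2)
    if not qs:
        return np.empty((0, size, size))
    return np.stack(qs)


def nucleus_mask(layout: SceneLayout, params: StainSceneParams) -> np.ndarray:
    """Boolean H×W union of all nucleus interiors."""
    q = _ellipse_quadform(layout, params.canvas_size)
    return (q <= 1.0).any(axis=0)


def membrane_mask(layout: SceneLayout, params: StainSceneParams) -> np.ndarray:
    """Boolean H×W membrane-ring region (ring band minus nucleus interiors)."""
    q = _ellipse_quadform(layout, params.canvas_size)
    in_ring = ((q > 1.0) & (q <= RING_SCALE ** 2)).any(axis=0)
    return in_ring & ~(q <= 1.0).any(axis=0)


def _flat_render(mask: np.ndarray, bg: np.ndarray, fg: np.ndarray) -> np.ndarray:
    img = np.empty(mask.shape + (3,))
    img[:] = bg
    img[mask] = fg
    return img


def render_source(layout: SceneLayout, params: StainSceneParams) -> np.ndarray:
    """HE-like render: eosin background, hematoxylin nuclei, Gaussian noise."""
    _, noise_rng, _ = _streams(params)
    img = _flat_render(nucleus_mask(layout, params), HE_BACKGROUND, HE_NUCLEUS)
    if params.noise_sd > 0:
        img = img + noise_rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_target(layout: SceneLayout, params: StainSceneParams) -> np.ndarray:
    """IHC-like render of the same geometry.

    Membrane rings are blended from the unstained background toward the DAB
    colour with weight grade/3, so stain intensity rises monotonically with
    grade and grade 0 carries no membrane stain at all.
    """
    _, _, noise_rng = _streams(params)
    img = _flat_render(nucleus_mask(layout, params), IHC_BACKGROUND, IHC_NUCLEUS)
    w = params.grade / 3.0
    if w > 0:
        ring = membrane_mask(layout, params)
        img[ring] = (1.0 - w) * IHC_BACKGROUND + w * DAB_BROWN
    if params.noise_sd > 0:
        img = img + noise_rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_pair(params: StainSceneParams):
    """Convenience: (source, target) arrays for one scene."""
    layout = sample_layout(params)
    return render_source(layout, params), render_target(layout, params)


def _apportion(n: int, proportions) -> list:
    """Largest-remainder apportionment of n items over the four grades."""
    p = np.asarray(proportions, dtype=float)
    if p.shape != (4,):
        raise ParameterError("grade_mix must have one proportion per grade (4)")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ParameterError("grade_mix must be nonnegative and sum to 1")
    raw = n * p
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts.tolist()


def scene_params_list(n_pairs: int, grade_mix,
                      base_params: StainSceneParams) -> list:
    """Per-pair scene parameters for a dataset: grades apportioned to the
    requested mix (largest remainder, exact when divisible), order shuffled
    and per-pair seeds drawn from a child stream of the base seed."""
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    counts = _apportion(n_pairs, grade_mix)
    grades = [g for g, c in zip(GRADES, counts) for _ in range(c)]
    mix_rng = np.random.default_rng(
        np.random.SeedSequence(base_params.seed, spawn_key=(1000,)))
    grades = [grades[i] for i in mix_rng.permutation(n_pairs)]
    pair_seeds = mix_rng.integers(0, 2 ** 31 - 1, size=n_pairs)
    return [dataclasses.replace(base_params, grade=int(g), seed=int(s))
            for g, s in zip(grades, pair_seeds)]


def generate_pairs(n_pairs: int, grade_mix, base_params: StainSceneParams,
                   id_prefix: str = "pair") -> list:
    """In-memory dataset: a list of ``ImagePair`` objects, fully seeded."""
    from .image_io import ImagePair

    pairs = []
    for i, params in enumerate(scene_params_list(n_pairs, grade_mix, base_params)):
        src, tgt = render_pair(params)
        pairs.append(ImagePair(source=src, target=tgt,
                               id=f"{id_prefix}_{i:04d}", grade=params.grade))
    return pairs


def generate_dataset(n_pairs: int, grade_mix, base_params: StainSceneParams,
                     out_dir, dialect: str = "paired_dirs") -> list:
    """Write ``n_pairs`` paired images plus a CSV manifest; fully seeded.

    dialect "paired_dirs" writes ``out/A/{name}.png`` (source) and
    ``out/B/{name}.png`` (target); "side_by_side" writes one double-width
    PNG per pair with the source on the left half.  Returns the manifest as
    a list of records (name, grade, seed, path(s)).
    """
    from . import image_io

    if dialect not in ("paired_dirs", "side_by_side"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    params_list = scene_params_list(n_pairs, grade_mix, base_params)

    out_dir = os.fspath(out_dir)
    try:
        if dialect == "paired_dirs":
            os.makedirs(os.path.join(out_dir, "A"), exist_ok=True)
            os.makedirs(os.path.join(out_dir, "B"), exist_ok=True)
        else:
            os.makedirs(out_dir, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out_dir}: {e}") from e

    manifest = []
    for i, params in enumerate(params_list):
        name = f"pair_{i:04d}"
        src, tgt = render_pair(params)
        rec = {"name": name, "grade": params.grade, "seed": params.seed}
        if dialect == "paired_dirs":
            pa = os.path.join(out_dir, "A", f"{name}.png")
            pb = os.path.join(out_dir, "B", f"{name}.png")
            image_io.save_image(src, pa)
            image_io.save_image(tgt, pb)
            rec.update(source_path=pa, target_path=pb)
        else:
            p = os.path.join(out_dir, f"{name}.png")
            image_io.save_image(np.concatenate([src, tgt], axis=1), p)
            rec.update(path=p)
        manifest.append(rec)

    with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["name", "grade", "seed"])
        writer.writeheader()
        for rec in manifest:
            writer.writerow({k: rec[k] for k in ("name", "grade", "seed")})
    return manifest
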