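"""Synthetic paired-stain generator: determinism, geometry, grade response."""

import dataclasses

import numpy as np
import pytest

import stainshift as ss
from stainshift import synthetic
from stainshift.errors import ParameterError


class TestLayout:
    def test_fixed_seed_reproduces_layout(self, tiny_scene):
        a = ss.sample_layout(tiny_scene)
        b = ss.sample_layout(tiny_scene)
        assert a == b

    def test_zero_nuclei_gives_empty_layout(self, tiny_scene):
        p = dataclasses.replace(tiny_scene, n_nuclei=0)
        assert ss.sample_layout(p).nuclei == ()

    def test_different_seeds_differ(self, tiny_scene):
        a = ss.sample_layout(dataclasses.replace(tiny_scene, seed=7, n_nuclei=10))
        b = ss.sample_layout(dataclasses.replace(tiny_scene, seed=8, n_nuclei=10))
        assert a != b

    def test_ellipses_inside_canvas(self, tiny_scene):
        layout = ss.sample_layout(tiny_scene)
        s = tiny_scene.canvas_size
        for cx, cy, rx, ry, _ in layout.nuclei:
            assert 0 < cx < s and 0 < cy < s
            assert rx > 0 and ry > 0
            assert cx - max(rx, ry) >= 0 and cx + max(rx, ry) <= s

    @pytest.mark.parametrize("bad", [
        dict(canvas_size=8), dict(n_nuclei=-1), dict(noise_sd=0.6),
        dict(grade=5), dict(nucleus_radius_range=(0.0, 3.0)),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            ss.StainSceneParams(**bad)


class TestRenderSource:
    def test_empty_noiseless_scene_is_flat_background(self):
        p = ss.StainSceneParams(canvas_size=32, n_nuclei=0, noise_sd=0.0, seed=0)
        img = ss.render_source(ss.sample_layout(p), p)
        assert np.all(img == synthetic.HE_BACKGROUND)

    def test_nucleus_center_pixel_has_nucleus_color(self):
        p = ss.StainSceneParams(canvas_size=32, n_nuclei=0, noise_sd=0.0, seed=0)
        layout = ss.SceneLayout(nuclei=((16.0, 16.0, 5.0, 5.0, 0.0),))
        img = ss.render_source(layout, p)
        assert np.all(img[16, 16] == synthetic.HE_NUCLEUS)

    def test_noise_sd_matches_request(self):
        # one huge nucleus -> >=1e4 interior pixels far from the clip bounds
        p = ss.StainSceneParams(canvas_size=128, n_nuclei=0, noise_sd=0.05, seed=3)
        layout = ss.SceneLayout(nuclei=((64.0, 64.0, 60.0, 60.0, 0.0),))
        clean = ss.render_source(layout, dataclasses.replace(p, noise_sd=0.0))
        noisy = ss.render_source(layout, p)
        interior = ss.synthetic.nucleus_mask(layout, p)
        assert interior.sum() * 3 >= 10_000
        resid = (noisy - clean)[interior]
        assert abs(resid.std() - 0.05) < 0.2 * 0.05


class TestRenderTarget:
    def test_grade0_has_no_membrane_stain(self):
        p = ss.StainSceneParams(canvas_size=48, n_nuclei=4, grade=0,
                                noise_sd=0.0, seed=5)
        layout = ss.sample_layout(p)
        img = ss.render_target(layout, p)
        stain = np.all(np.isclose(img, synthetic.DAB_BROWN), axis=-1)
        assert not stain.any()
        # every pixel is either background or nucleus colour
        bg = np.all(img == synthetic.IHC_BACKGROUND, axis=-1)
        nuc = np.all(img == synthetic.IHC_NUCLEUS, axis=-1)
        assert np.all(bg | nuc)

    def test_ring_intensity_monotone_in_grade(self):
        p0 = ss.StainSceneParams(canvas_size=48, n_nuclei=4, noise_sd=0.0, seed=5)
        layout = ss.sample_layout(p0)
        ring = ss.synthetic.membrane_mask(layout, p0)
        assert ring.any()
        # stain darkens the ring: mean ring intensity decreases with grade,
        # i.e. stain amount (distance from background) strictly increases
        amounts = []
        for g in range(4):
            img = ss.render_target(layout, dataclasses.replace(p0, grade=g))
            amounts.append(np.abs(img[ring] - synthetic.IHC_BACKGROUND).mean())
        assert amounts[0] == 0.0
        assert all(b > a for a, b in zip(amounts, amounts[1:]))
        assert amounts[3] > amounts[1]

    def test_geometry_shared_across_grades_and_with_source(self):
        base = ss.StainSceneParams(canvas_size=48, n_nuclei=6, noise_sd=0.0, seed=9)
        layouts = [ss.sample_layout(dataclasses.replace(base, grade=g))
                   for g in range(4)]
        assert all(l == layouts[0] for l in layouts)
        masks = [ss.synthetic.nucleus_mask(l, base) for l in layouts]
        assert all(np.array_equal(m, masks[0]) for m in masks)


class TestGenerateDataset:
    def test_uniform_mix_exact_counts(self, tmp_path, tiny_scene):
        manifest = ss.generate_dataset(8, (0.25,) * 4, tiny_scene,
                                       tmp_path / "d")
        grades = sorted(rec["grade"] for rec in manifest)
        assert grades == [0, 0, 1, 1, 2, 2, 3, 3]
        assert (tmp_path / "d" / "manifest.csv").exists()
        assert len(list((tmp_path / "d" / "A").glob("*.png"))) == 8

    def test_half_half_mix(self, tiny_scene, tmp_path):
        manifest = ss.generate_dataset(100, (0.5, 0.5, 0, 0), tiny_scene,
                                       tmp_path / "d")
        grades = [rec["grade"] for rec in manifest]
        assert grades.count(0) == 50 and grades.count(1) == 50

    def test_same_seed_byte_identical_files(self, tmp_path, tiny_scene):
        ss.generate_dataset(4, (0.25,) * 4, tiny_scene, tmp_path / "a",
                            dialect="side_by_side")
        ss.generate_dataset(4, (0.25,) * 4, tiny_scene, tmp_path / "b",
                            dialect="side_by_side")
        for fa in sorted((tmp_path / "a").glob("*")):
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes()

    def test_bad_mix_rejected(self, tiny_scene, tmp_path):
        with pytest.raises(ParameterError):
            ss.generate_dataset(4, (0.5, 0.5, 0.5, -0.5), tiny_scene, tmp_path)

    def test_in_memory_pairs_match_params(self, tiny_scene):
        pairs = ss.generate_pairs(8, (0, 0, 0, 1.0), tiny_scene)
        assert len(pairs) == 8
        assert all(p.grade == 3 for p in pairs)
        assert all(p.source.shape == (32, 32, 3) for p in pairs)
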