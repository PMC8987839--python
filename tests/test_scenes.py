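"""Synthetic scene generator: determinism, mask geometry, occupancy grids."""

import numpy as np
import pytest

import greenview as gv
from greenview.exceptions import GenerationError, InputError, SceneSpecError


def full_canvas_spec(category, size=128, seed=0):
    return gv.SceneSpec(
        width=size,
        height=size,
        regions=(gv.RegionSpec(category, (0, 0, size, size)),),
        seed=seed,
    )


class TestGenerateScene:
    def test_full_vegetation_mask_all_true(self):
        fx = gv.generate_scene(full_canvas_spec("vegetation"))
        assert fx.mask.all()

    def test_no_vegetation_mask_all_false(self):
        spec = gv.SceneSpec(
            width=96,
            height=96,
            regions=(
                gv.RegionSpec("sky", (0, 0, 96, 48)),
                gv.RegionSpec("artificial_green", (0, 48, 96, 96)),
            ),
            seed=3,
        )
        assert not gv.generate_scene(spec).mask.any()

    def test_deterministic_rerun_byte_identical(self):
        spec = gv.random_street_scene(seed=7)
        a, b = gv.generate_scene(spec), gv.generate_scene(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_off_canvas_region_rejected(self):
        with pytest.raises(SceneSpecError):
            gv.SceneSpec(
                width=64,
                height=64,
                regions=(gv.RegionSpec("road", (0, 0, 65, 64)),),
            )

    def test_texture_amplitudes_separate_vegetation_from_artificial(self):
        veg = gv.generate_scene(full_canvas_spec("vegetation", seed=1))
        art = gv.generate_scene(full_canvas_spec("artificial_green", seed=1))
        veg_std = veg.image.astype(float).std(axis=(0, 1)).mean()
        art_std = art.image.astype(float).std(axis=(0, 1)).mean()
        assert veg_std > 10 * art_std

    def test_shadow_vegetation_darker_but_still_greenery(self):
        veg = gv.generate_scene(full_canvas_spec("vegetation", seed=5))
        shadow = gv.generate_scene(full_canvas_spec("shadow_vegetation", seed=5))
        assert shadow.mask.all()
        ratio = shadow.image.mean() / veg.image.mean()
        assert 0.25 < ratio < 0.65

    def test_sky_gradient_brightens_downward(self):
        sky = gv.generate_scene(full_canvas_spec("sky", seed=2)).image
        assert sky[-1].mean() > sky[0].mean() + 30

    def test_mask_matches_independent_region_painting(self):
        spec = gv.random_street_scene(seed=11)
        fx = gv.generate_scene(spec)
        expect = np.zeros((spec.height, spec.width), dtype=bool)
        for r in spec.regions:  # same overwrite order, painted independently
            x0, y0, x1, y1 = r.box
            expect[y0:y1, x0:x1] = r.category in gv.GREENERY_CATEGORIES
        assert np.array_equal(fx.mask, expect)

    def test_category_mask_respects_overwrite_order(self):
        spec = gv.SceneSpec(
            width=64,
            height=64,
            regions=(
                gv.RegionSpec("vegetation", (0, 0, 64, 64)),
                gv.RegionSpec("road", (0, 32, 64, 64)),
            ),
        )
        fx = gv.generate_scene(spec)
        veg = gv.category_mask(fx, "vegetation")
        assert veg[:32].all() and not veg[32:].any()


class TestMaskToGridLabels:
    def test_all_true_640_gives_20x20_all_true(self):
        grid = gv.mask_to_grid_labels(np.ones((640, 640), bool))
        assert grid.shape == (20, 20) and grid.all()

    def test_exact_half_cell_is_negative(self):
        mask = np.zeros((32, 32), bool)
        mask[:16, :] = True  # exactly 512 of 1024 pixels
        assert not gv.mask_to_grid_labels(mask)[0, 0]

    def test_left_half_true_64px(self):
        mask = np.zeros((64, 64), bool)
        mask[:, :32] = True
        grid = gv.mask_to_grid_labels(mask)
        assert grid.shape == (2, 2)
        assert grid[:, 0].all() and not grid[:, 1].any()

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(25):
            h, w = rng.integers(32, 130, size=2)
            cell = int(rng.choice([8, 16, 32]))
            mask = rng.random((h, w)) < rng.random()
            grid = gv.mask_to_grid_labels(mask, cell_px=cell)
            rows, cols = h // cell, w // cell
            assert grid.shape == (rows, cols)
            for r in range(rows):
                for c in range(cols):
                    block = mask[r * cell : (r + 1) * cell, c * cell : (c + 1) * cell]
                    assert grid[r, c] == (block.mean() > 0.5)

    def test_invalid_cell_size_rejected(self):
        with pytest.raises(InputError):
            gv.mask_to_grid_labels(np.ones((64, 64), bool), cell_px=0)

    def test_mask_smaller_than_cell_rejected(self):
        with pytest.raises(InputError):
            gv.mask_to_grid_labels(np.ones((16, 64), bool), cell_px=32)


class TestSceneToAnnotations:
    def test_counts_and_labels(self, street_fixture):
        anns = gv.scene_to_annotations(street_fixture, 3, 5, seed=9)
        assert len(anns) == 8
        assert sum(a.label for a in anns) == 3

    def test_positive_rectangles_meet_purity_on_remeasure(self, street_fixture):
        anns = gv.scene_to_annotations(street_fixture, 5, 5, purity=0.9, seed=4)
        mask = street_fixture.mask
        for a in anns:
            frac = mask[a.y0 : a.y1, a.x0 : a.x1].mean()
            if a.label:
                assert frac >= 0.9
            else:
                assert frac <= 0.1

    def test_infeasible_class_raises_named_error(self):
        fx = gv.generate_scene(full_canvas_spec("vegetation"))
        with pytest.raises(GenerationError, match="negative"):
            gv.scene_to_annotations(fx, 0, 1, seed=0)

    def test_deterministic_per_seed(self, street_fixture):
        a = gv.scene_to_annotations(street_fixture, 2, 2, seed=77)
        b = gv.scene_to_annotations(street_fixture, 2, 2, seed=77)
        assert a == b


class TestFixtureIO:
    def test_roundtrip(self, tmp_path, street_fixture):
        paths = gv.write_fixture(street_fixture, tmp_path, "fx")
        spec = gv.read_spec(paths["spec"])
        assert spec == street_fixture.spec
        from PIL import Image

        img = np.asarray(Image.open(paths["image"]))
        mask = np.asarray(Image.open(paths["mask"])) > 127
        assert np.array_equal(img, street_fixture.image)
        assert np.array_equal(mask, street_fixture.mask)
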