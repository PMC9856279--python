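"""Preprocessing: IO, cropping, scaling, slicing, augmentation, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mstcell as M
from mstcell.preprocess import (augment_flips, canonicalize, crop_scale_bar,
                                divide_expand, load_image, make_slices,
                                prepare_bundle, save_image, scale_pixels,
                                split_dataset)
from mstcell.synthetic import PhenotypeSpec, generate_image, stamp_scale_bar
from mstcell.types import CellClass, LabeledImage


def _dummy(label=CellClass.IPSC, side=64, value=100, sid="img"):
    return LabeledImage(pixels=np.full((side, side, 3), value, dtype=np.uint8),
                        label=label, source_id=sid)


class TestLoadImage:
    def test_grayscale_tiff_replicated(self, tmp_path):
        import tifffile
        arr = np.arange(100 * 100, dtype=np.uint8).reshape(100, 100) % 251
        tifffile.imwrite(tmp_path / "g.tif", arr)
        img = load_image(tmp_path / "g.tif", label="MSC")
        assert img.pixels.shape == (100, 100, 3)
        assert np.array_equal(img.pixels[..., 0], img.pixels[..., 1])
        assert np.array_equal(img.pixels[..., 0], arr)

    def test_rgba_png_alpha_dropped(self, tmp_path):
        from PIL import Image
        rgba = np.random.default_rng(0).integers(
            0, 255, size=(64, 64, 4)).astype(np.uint8)
        Image.fromarray(rgba, "RGBA").save(tmp_path / "a.png")
        img = load_image(tmp_path / "a.png", label="RGC")
        assert img.pixels.shape == (64, 64, 3)
        assert np.array_equal(img.pixels, rgba[..., :3])

    def test_png_save_load_round_trip(self, tmp_path):
        src = generate_image(PhenotypeSpec(CellClass.RPE, canvas_side=64,
                                           rpe_degree=0.4, seed=9))
        save_image(src, tmp_path / "x.png")
        back = load_image(tmp_path / "x.png", label="RPE")
        assert np.array_equal(back.pixels, src.pixels)

    def test_16bit_tiff_rescaled(self, tmp_path):
        import tifffile
        arr = np.full((64, 64), 65535, dtype=np.uint16)
        tifffile.imwrite(tmp_path / "deep.tif", arr)
        img = load_image(tmp_path / "deep.tif", label="IPSC")
        assert img.pixels.dtype == np.uint8
        assert img.pixels.max() == 255

    def test_label_from_directory(self, tmp_path):
        from PIL import Image
        d = tmp_path / "RPE"
        d.mkdir()
        Image.fromarray(np.zeros((64, 64, 3), np.uint8)).save(d / "x.png")
        assert load_image(d / "x.png").label is CellClass.RPE

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.png"):
            load_image(tmp_path / "nope.png", label="IPSC")


class TestCropScaleBar:
    def test_zero_margin_identity(self):
        img = _dummy(side=100)
        out = crop_scale_bar(img, 0.0)
        assert np.array_equal(out.pixels, img.pixels)

    def test_margin_arithmetic_512(self):
        img = _dummy(side=512)
        out = crop_scale_bar(img, 0.05)
        assert out.pixels.shape == (462, 462, 3)   # 512 - 2*floor(512*0.05)

    def test_removes_corner_bar(self):
        img = generate_image(PhenotypeSpec(CellClass.MSC, canvas_side=512,
                                           seed=8))
        stamped = stamp_scale_bar(img, "bottom_right", (80, 12))
        out = crop_scale_bar(stamped, 0.05)
        bar_mask = (out.pixels > 240).all(axis=2)
        assert bar_mask.sum() == 0
        assert not out.has_scale_bar

    def test_margin_bounds(self):
        with pytest.raises(ValueError):
            crop_scale_bar(_dummy(), 0.25)
        with pytest.raises(ValueError):
            crop_scale_bar(_dummy(), -0.01)


class TestCanonicalize:
    def test_same_size_noop(self):
        img = generate_image(PhenotypeSpec(CellClass.IPSC, canvas_side=512,
                                           seed=1))
        t = canonicalize(img)
        assert t.shape == (512, 512, 3)
        assert np.array_equal(t, img.pixels.astype(float))

    def test_constant_stays_constant(self):
        t = canonicalize(_dummy(side=1024, value=77))
        assert t.shape == (512, 512, 3)
        np.testing.assert_allclose(t, 77.0)

    def test_arbitrary_aspect_resized(self):
        img = LabeledImage(np.zeros((480, 640, 3), np.uint8), CellClass.MSC)
        assert canonicalize(img).shape == (512, 512, 3)


class TestScalePixels:
    @pytest.mark.parametrize("value,zero_one,sym_one",
                             [(0, 0.0, -1.0), (255, 1.0, 1.0),
                              (127.5, 0.5, 0.0)])
    def test_boundaries_and_midpoint(self, value, zero_one, sym_one):
        t = np.full((2, 2, 3), value, dtype=float)
        assert scale_pixels(t, "zero_one")[0, 0, 0] == pytest.approx(zero_one)
        assert scale_pixels(t, "sym_one")[0, 0, 0] == pytest.approx(sym_one)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scale_pixels(np.full((2, 2, 3), 300.0), "zero_one")
        with pytest.raises(ValueError):
            scale_pixels(np.zeros((2, 2, 3)), "tanh")


class TestMakeSlices:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_partition_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(-1, 1, size=(64, 64, 3))
        bundle = make_slices(t, "sym_one")
        assert np.array_equal(bundle.reassembled(), t)
        assert np.array_equal(bundle.macro, t)

    def test_constant_input_constant_slices(self):
        bundle = make_slices(np.full((64, 64, 3), 0.5), "zero_one")
        for q in [bundle.macro] + bundle.quadrants:
            np.testing.assert_allclose(q, 0.5)

    def test_single_pixel_lands_in_top_right(self):
        t = np.zeros((512, 512, 3))
        t[10, 300, 0] = 1.0                        # col 300 >= 256 -> TR
        bundle = make_slices(t, "zero_one")
        tl, tr, bl, br = bundle.quadrants
        assert tr.sum() == 1.0 and tr[10, 44, 0] == 1.0
        assert tl.sum() == bl.sum() == br.sum() == 0.0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            make_slices(np.zeros((64, 32, 3)), "zero_one")

    def test_prepare_bundle_composition_invariants(self):
        img = generate_image(PhenotypeSpec(CellClass.RGC, canvas_side=150,
                                           seed=3))
        bundle = prepare_bundle(img, "sym_one", side=128, crop_margin=0.05)
        assert bundle.macro.shape == (128, 128, 3)
        assert -1.0 <= bundle.macro.min() and bundle.macro.max() <= 1.0
        assert np.array_equal(bundle.reassembled(), bundle.macro)


class TestAugmentFlips:
    @pytest.mark.parametrize("n_in,n_out", [(401, 1604), (370, 1480)])
    def test_published_4x_counts(self, n_in, n_out):
        imgs = [_dummy(sid=f"s{i}") for i in range(n_in)]
        assert len(augment_flips(imgs)) == n_out

    def test_class_proportions_conserved(self):
        imgs = ([_dummy(CellClass.IPSC, sid=f"a{i}") for i in range(3)]
                + [_dummy(CellClass.RPE, sid=f"b{i}") for i in range(5)])
        out = augment_flips(imgs)
        assert sum(im.label is CellClass.IPSC for im in out) == 12
        assert sum(im.label is CellClass.RPE for im in out) == 20

    def test_hv_flip_is_involution(self):
        img = generate_image(PhenotypeSpec(CellClass.MSC, canvas_side=64,
                                           seed=6))
        hv = np.flip(np.flip(img.pixels, axis=0), axis=1)
        assert np.array_equal(np.flip(np.flip(hv, axis=0), axis=1), img.pixels)
        variants = augment_flips([img])
        assert len(variants) == 4
        assert {v.source_id.split(":")[-1] for v in variants} == \
            {"orig", "h", "v", "hv"}
        assert np.array_equal(variants[3].pixels, hv)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            augment_flips([])


class TestDivideExpand:
    def test_count_contract_5x(self):
        imgs = [_dummy(sid=f"s{i}") for i in range(10)]
        assert len(divide_expand(imgs)) == 50

    def test_constant_image_constant_samples(self):
        out = divide_expand([_dummy(value=42)])
        for s in out:
            np.testing.assert_allclose(s.pixels, 42)

    def test_quadrant_pigment_matches_parent_quadrant(self):
        from tests.test_synthetic import oracle_pigment_fraction
        img = generate_image(PhenotypeSpec(CellClass.RPE, canvas_side=256,
                                           rpe_degree=0.4, seed=12))
        out = divide_expand([img])
        h = 128
        parents = [img.pixels[:h, :h], img.pixels[:h, h:],
                   img.pixels[h:, :h], img.pixels[h:, h:]]
        for sample, parent in zip(out[1:], parents):
            assert abs(oracle_pigment_fraction(sample.pixels)
                       - oracle_pigment_fraction(parent)) <= 0.02


class TestSplitDataset:
    def test_published_split_arithmetic(self):
        """1291 training sources -> 5164 augmented, 1032 validation."""
        imgs = [_dummy(sid=f"s{i}") for i in range(1938)]
        split = split_dataset(imgs, train_frac=1291 / 1938,
                              val_frac_of_augmented=0.20, seed=0)
        assert len(split.test) == 647
        assert len(split.train) + len(split.val) == 5164
        assert len(split.val) == 1032

    def test_test_sources_never_in_train(self):
        imgs = [_dummy(sid=f"s{i}") for i in range(40)]
        split = split_dataset(imgs, 0.5, 0.25, seed=1)
        test_ids = {im.source_id for im in split.test}
        train_ids = {im.source_id.split(":")[0] for im in split.train}
        val_ids = {im.source_id.split(":")[0] for im in split.val}
        assert test_ids.isdisjoint(train_ids)
        assert test_ids.isdisjoint(val_ids)

    def test_reproducible(self):
        imgs = [_dummy(sid=f"s{i}") for i in range(30)]
        a = split_dataset(imgs, 0.6, 0.2, seed=7)
        b = split_dataset(imgs, 0.6, 0.2, seed=7)
        for part in ("train", "val", "test"):
            assert [im.source_id for im in getattr(a, part)] == \
                [im.source_id for im in getattr(b, part)]

    def test_fraction_validation(self):
        imgs = [_dummy(sid=f"s{i}") for i in range(10)]
        with pytest.raises(ValueError):
            split_dataset(imgs, 0.0)
        with pytest.raises(ValueError):
            split_dataset(imgs, 0.5, 1.0)
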