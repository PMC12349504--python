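"""Augmentation operators: letterbox, CutMix, GridMask, small-object boost,
pyramid and jitter."""

import numpy as np
import pytest

from pestpair import sample_scene
from pestpair.augment import (
    JitterConfig,
    build_pyramid,
    cutmix,
    gridmask,
    photometric_geometric_jitter,
    resize_letterbox,
    small_object_boost,
)


def _const_image(h, w, value=100):
    return np.full((h, w, 3), value, dtype=np.uint8)


class _Sample:
    def __init__(self, image, labels, boxes=()):
        self.image = image
        self.labels = np.asarray(labels)
        self.boxes = list(boxes)


class TestLetterbox:
    def test_landscape_pads_vertically(self):
        img = np.zeros((768, 1024, 3), dtype=np.uint8)
        img[...] = 200
        out = resize_letterbox(img, 224, 224, fill=(0, 0, 0))
        assert out.shape == (224, 224, 3)
        # content is 224x168 centred: 28 pad rows top and bottom
        assert np.all(out[:28] == 0) and np.all(out[-28:] == 0)
        assert np.all(out[28:196] == 200)

    def test_identity_resize(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (224, 224, 3), dtype=np.uint8)
        out = resize_letterbox(img, 224, 224)
        assert np.array_equal(out, img)

    def test_tall_content_pads_horizontally_with_boxes(self):
        img = _const_image(100, 50, 130)
        out, boxes = resize_letterbox(img, 224, 224, boxes=[(0, 10, 20, 30, 40)], fill=(1, 2, 3))
        assert out.shape == (224, 224, 3)
        assert np.all(out[:, :56] == (1, 2, 3)) and np.all(out[:, -56:] == (1, 2, 3))
        # boxes follow the same scale (2.24) and offset (56, 0)
        c, x0, y0, x1, y1 = boxes[0]
        assert (x0, y0, x1, y1) == (round(10 * 2.24) + 56, round(20 * 2.24), round(30 * 2.24) + 56, round(40 * 2.24))

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            resize_letterbox(np.empty((0, 0, 3), dtype=np.uint8), 32, 32)


class TestCutMix:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.a = _Sample(rng.integers(0, 255, (64, 64, 3), dtype=np.uint8), [1, 0, 0])
        self.b = _Sample(rng.integers(0, 255, (64, 64, 3), dtype=np.uint8), [0, 1, 0])

    def test_full_mask_returns_source_a(self):
        out = cutmix(self.a, self.b, region=(0, 0, 64, 64))
        assert np.array_equal(out.image, self.a.image)
        assert np.allclose(out.soft_labels, self.a.labels)

    def test_empty_mask_returns_source_b(self):
        out = cutmix(self.a, self.b, region=(0, 0, 0, 0))
        assert np.array_equal(out.image, self.b.image)
        assert np.allclose(out.soft_labels, self.b.labels)

    def test_quarter_region_area_weighted_labels(self):
        out = cutmix(self.a, self.b, region=(0, 0, 32, 32))  # 25% of pixels
        assert np.allclose(out.soft_labels, [0.25, 0.75, 0.0])

    def test_pixel_conservation(self):
        out = cutmix(self.a, self.b, region=(5, 9, 40, 50))
        from_a = (out.image == self.a.image).all(axis=2)
        from_b = (out.image == self.b.image).all(axis=2)
        assert np.all(from_a | from_b)

    def test_label_contributions_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            out = cutmix(self.a, self.b, rng=rng)
            lam = float(out.provenance[0].split("lam=")[1].rstrip(")"))
            # the two source contributions sum to lam + (1 - lam) = 1
            assert np.isclose(out.soft_labels.sum(), 1.0)
            assert np.allclose(
                out.soft_labels, lam * self.a.labels + (1 - lam) * self.b.labels, atol=1e-3
            )

    def test_box_clipping_and_drop(self):
        a = _Sample(self.a.image, [1, 0, 0], [(0, 0, 0, 10, 10)])
        b = _Sample(self.b.image, [0, 1, 0], [(1, 0, 0, 10, 10), (1, 50, 50, 60, 60)])
        out = cutmix(a, b, region=(0, 0, 32, 32))
        cats = [bx[0] for bx in out.boxes]
        assert 0 in cats  # A's box inside the region survives
        assert (1, 50, 50, 60, 60) in out.boxes  # B's far box survives
        assert (1, 0, 0, 10, 10) not in out.boxes  # B's covered box dropped

    def test_shape_mismatch_rejected(self):
        small = _Sample(_const_image(32, 32), [0, 0, 1])
        with pytest.raises(ValueError, match="identical shape"):
            cutmix(self.a, small)


class TestGridMask:
    def test_keep_one_is_identity(self):
        img = _const_image(64, 64, 77)
        assert np.array_equal(gridmask(img, 8, 1.0), img)

    def test_keep_zero_blanks_everything(self):
        img = _const_image(64, 64, 77)
        assert np.all(gridmask(img, 8, 0.0) == 0)

    def test_masked_pixel_count_by_enumeration(self):
        img = _const_image(64, 64, 255)
        out = gridmask(img, 8, 0.5, offsets=(0, 0))
        # direct enumeration of the periodic mask
        expected = np.zeros((64, 64), dtype=bool)
        for y in range(64):
            for x in range(64):
                expected[y, x] = (y % 8) < 4 and (x % 8) < 4
        zeroed = (out == 0).all(axis=2)
        assert np.array_equal(zeroed, expected)
        assert zeroed.sum() == 1024

    def test_idempotent_on_mask_support(self):
        rng = np.random.default_rng(5)
        img = rng.integers(1, 255, (64, 64, 3), dtype=np.uint8)
        once = gridmask(img, 8, 0.6, offsets=(2, 3))
        twice = gridmask(once, 8, 0.6, offsets=(2, 3))
        assert np.array_equal(once, twice)

    def test_unit_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            gridmask(_const_image(32, 32), 64, 0.5)

    def test_unit_below_two_rejected(self):
        with pytest.raises(ValueError):
            gridmask(_const_image(32, 32), 1, 0.5)


class TestSmallObjectBoost:
    def test_copies_appended(self):
        img = _const_image(64, 64, 40)
        img[2:6, 2:6] = 250
        s = _Sample(img, [1, 0], [(0, 2, 2, 6, 6)])  # 16/4096 < 0.5%
        out = small_object_boost(s, n_copies=2, scale_factor=1.5, rng=np.random.default_rng(0))
        assert len(out.boxes) == 3
        assert all(b[0] == 0 for b in out.boxes)
        assert np.array_equal(out.soft_labels, s.labels)

    def test_no_small_boxes_is_noop(self):
        img = _const_image(64, 64, 40)
        s = _Sample(img, [1, 0], [(0, 0, 0, 40, 40)])  # large box
        out = small_object_boost(s, n_copies=3, scale_factor=2.0, rng=np.random.default_rng(0))
        assert out.boxes == s.boxes
        assert np.array_equal(out.image, img)

    def test_small_box_count_not_reduced(self, schema, cooc):
        rng = np.random.default_rng(8)
        thr = 0.005 * 64 * 64
        for seed in range(10):
            s = sample_scene(schema, cooc, 64, rng_seed=seed)
            before = sum(1 for b in s.boxes if (b[3] - b[1]) * (b[4] - b[2]) < thr)
            out = small_object_boost(s, n_copies=1, scale_factor=1.2, rng=rng)
            after = sum(1 for b in out.boxes if (b[3] - b[1]) * (b[4] - b[2]) < thr)
            assert after >= before

    def test_scaled_copies_do_not_overlap_originals(self):
        img = _const_image(64, 64, 40)
        img[2:6, 2:6] = 250
        s = _Sample(img, [1], [(0, 2, 2, 6, 6)])
        out = small_object_boost(s, n_copies=4, scale_factor=2.0, rng=np.random.default_rng(1))
        news = out.boxes[1:]
        for _, x0, y0, x1, y1 in news:
            ow = max(0, min(6, x1) - max(2, x0))
            oh = max(0, min(6, y1) - max(2, y0))
            assert ow * oh == 0


class TestPyramid:
    def test_stated_scale_set(self):
        img = _const_image(224, 224)
        pyr = build_pyramid(img, [0.5, 1.0, 1.5])
        assert [im.shape[0] for im in pyr.images] == [112, 224, 336]

    def test_singleton_scale_is_original(self):
        img = _const_image(64, 64, 9)
        pyr = build_pyramid(img, [1.0])
        assert np.array_equal(pyr.images[0], img)

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            build_pyramid(_const_image(64, 64), [])

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            build_pyramid(_const_image(64, 64), [1.0, -0.5])


class TestJitter:
    def test_zero_magnitudes_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        cfg = JitterConfig(brightness=0, crop=0, hflip=False, rotate_deg=0)
        out = photometric_geometric_jitter(img, cfg, np.random.default_rng(0))
        assert np.array_equal(out, img)

    def test_brightness_scaling_with_clipping(self):
        img = _const_image(32, 32, 100)
        cfg = JitterConfig(brightness=0, crop=0, hflip=False, rotate_deg=0)
        out = photometric_geometric_jitter(img, cfg, np.random.default_rng(0), brightness_scale=1.2)
        assert np.all(out == 120)
        bright = _const_image(32, 32, 240)
        out = photometric_geometric_jitter(bright, cfg, np.random.default_rng(0), brightness_scale=1.2)
        assert np.all(out == 255)

    def test_seeded_determinism(self):
        img = np.random.default_rng(4).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        cfg = JitterConfig()
        a = photometric_geometric_jitter(img, cfg, np.random.default_rng(11))
        b = photometric_geometric_jitter(img, cfg, np.random.default_rng(11))
        assert np.array_equal(a, b)


class TestBoxBoundsProperty:
    def test_augmented_boxes_stay_in_bounds(self, schema, cooc):
        """Brute-force bound check across many randomly augmented samples."""
        rng = np.random.default_rng(77)
        scenes = [sample_scene(schema, cooc, 64, rng_seed=s) for s in range(40)]
        checked = 0
        for _ in range(1000):
            a, b = rng.choice(len(scenes), 2, replace=False)
            out = cutmix(scenes[a], scenes[b], rng=rng)
            out = small_object_boost(out, n_copies=1, scale_factor=1.3, rng=rng)
            h, w = out.image.shape[:2]
            for _, x0, y0, x1, y1 in out.boxes:
                assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h
            checked += 1
        assert checked == 1000
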