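"""Augmentation operators: identity no-ops, box bookkeeping, convexity,
copy-paste constraints and reproducibility under composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pestlite.augment import (AugmentConfig, Augmenter, color_jitter,
                              copy_paste_small, crop_resize, cutout,
                              extract_small_objects, mixup, mosaic)
from pestlite.data import AnnotatedImage, box_iou

rng = np.random.default_rng(0)


def _img(h=32, w=32, boxes=((4, 4, 12, 12),), labels=(0,)):
    return AnnotatedImage(rng.uniform(0, 1, (h, w, 3)),
                          np.array(boxes, dtype=float).reshape(-1, 4),
                          np.array(labels, dtype=np.int64))


# ---------------------------------------------------------------------------
# color jitter
# ---------------------------------------------------------------------------

def test_neutral_color_jitter_is_bitwise_identity():
    img = _img()
    out = color_jitter(img, 1.0, 1.0, 1.0, 0.0)
    assert np.array_equal(out.pixels, img.pixels)
    assert np.array_equal(out.boxes, img.boxes)


def test_brightness_doubles_midgray_before_clipping():
    img = _img()
    img.pixels[:] = 0.4
    out = color_jitter(img, alpha=2.0)
    assert np.allclose(out.pixels, 0.8)


def test_color_jitter_never_moves_boxes_and_stays_in_range():
    img = _img()
    out = color_jitter(img, 1.9, 0.5, 1.4, 0.05)
    assert np.array_equal(out.boxes, img.boxes)
    assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


# ---------------------------------------------------------------------------
# cutout
# ---------------------------------------------------------------------------

def test_cutout_zero_mask_is_identity():
    img = _img()
    out = cutout(img, np.zeros((32, 32)))
    assert np.array_equal(out.pixels, img.pixels)
    assert len(out.boxes) == 1


def test_cutout_full_mask_blanks_image_and_drops_boxes():
    img = _img()
    out = cutout(img, np.ones((32, 32)))
    assert not out.pixels.any()
    assert len(out.boxes) == 0


def test_cutout_pixel_count_exact():
    img = _img(4, 4, boxes=np.zeros((0, 4)), labels=())
    m = np.zeros((4, 4))
    m[:2, :2] = 1
    out = cutout(img, m)
    assert (out.pixels == 0).all(axis=2).sum() == 4


def test_cutout_mask_size_mismatch_rejected():
    with pytest.raises(ValueError, match="mask"):
        cutout(_img(), np.zeros((8, 8)))


# ---------------------------------------------------------------------------
# crop & resize
# ---------------------------------------------------------------------------

def test_full_window_identity_keeps_pixels_and_boxes():
    img = _img()
    out = crop_resize(img, (0, 0, 32, 32), (32, 32))
    assert np.array_equal(out.pixels, img.pixels)
    assert np.allclose(out.boxes, img.boxes)


def test_crop_zoom_scales_small_boxes_up():
    """A 10-px pest inside a 100-px crop resized to 640 becomes 64 px."""
    img = _img(200, 200, boxes=((50, 50, 60, 60),))
    out = crop_resize(img, (20, 20, 120, 120), (640, 640))
    b = out.boxes[0]
    assert b[2] - b[0] == pytest.approx(64.0)
    assert b[3] - b[1] == pytest.approx(64.0)


def test_box_fully_outside_window_dropped():
    img = _img(boxes=((20, 20, 28, 28),))
    out = crop_resize(img, (0, 0, 16, 16), (32, 32))
    assert len(out.boxes) == 0


def test_window_outside_image_rejected():
    with pytest.raises(ValueError, match="window"):
        crop_resize(_img(), (0, 0, 40, 40), (32, 32))


# ---------------------------------------------------------------------------
# mosaic
# ---------------------------------------------------------------------------

def test_mosaic_center_tiling_of_identical_sources():
    img = _img(16, 16, boxes=((6, 6, 10, 10),))
    out = mosaic([img] * 4, (16, 16), center=(16.0, 16.0))
    assert out.pixels.shape == (16, 16, 3)
    # center tiling: each 8x8 quadrant is a half-scale crop of the source
    q = out.pixels[:8, :8]
    q2 = out.pixels[:8, 8:]
    assert q.shape == q2.shape == (8, 8, 3)


def test_mosaic_output_size_fixed_and_empty_sources_contribute_nothing():
    imgs = [_img(16, 16, boxes=np.zeros((0, 4)), labels=()) for _ in range(4)]
    out = mosaic(imgs, (16, 16), center=(16.0, 16.0))
    assert out.pixels.shape == (16, 16, 3) and len(out.boxes) == 0


def test_mosaic_requires_four_images():
    with pytest.raises(ValueError, match="4"):
        mosaic([_img()] * 3, (16, 16))


def test_mosaic_center_constrained_to_central_region():
    with pytest.raises(ValueError, match="central"):
        mosaic([_img(16, 16)] * 4, (16, 16), center=(2.0, 2.0))


# ---------------------------------------------------------------------------
# mixup
# ---------------------------------------------------------------------------

def test_mixup_endpoints_and_midpoint():
    a, b = _img(), _img()
    assert np.array_equal(mixup(a, b, 1.0).pixels, a.pixels)
    a.pixels[:] = 0.2
    b.pixels[:] = 0.6
    assert np.allclose(mixup(a, b, 0.5).pixels, 0.4)


def test_mixup_union_annotations_with_weights():
    a = _img(boxes=((1, 1, 5, 5),), labels=(0,))
    b = _img(boxes=((8, 8, 14, 14),), labels=(1,))
    out = mixup(a, b, 0.3)
    assert len(out.boxes) == 2
    assert out.weights == pytest.approx([0.3, 0.7])


@given(lam=st.floats(0.0, 1.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_mixup_pixels_bounded_by_inputs(lam):
    a = AnnotatedImage(rng.uniform(0, 1, (8, 8, 3)), np.zeros((0, 4)), [])
    b = AnnotatedImage(rng.uniform(0, 1, (8, 8, 3)), np.zeros((0, 4)), [])
    out = mixup(a, b, lam)
    lo, hi = np.minimum(a.pixels, b.pixels), np.maximum(a.pixels, b.pixels)
    assert (out.pixels >= lo - 1e-12).all() and (out.pixels <= hi + 1e-12).all()


def test_beta_symmetric_sampling_mean():
    draws = np.random.default_rng(123).beta(1.0, 1.0, size=10_000)
    assert abs(draws.mean() - 0.5) < 0.02


# ---------------------------------------------------------------------------
# copy–paste
# ---------------------------------------------------------------------------

def _donors():
    donor_img = _img(40, 40, boxes=((10, 10, 18, 17),), labels=(1,))
    return extract_small_objects([donor_img])


def test_copy_paste_zero_n_is_identity():
    cfg = AugmentConfig(copy_paste_n=(0, 0))
    img = _img(64, 64)
    out = copy_paste_small(img, _donors(), cfg, np.random.default_rng(0))
    assert np.array_equal(out.pixels, img.pixels)
    assert len(out.boxes) == len(img.boxes)


def test_copy_paste_empty_pool_warns_noop():
    cfg = AugmentConfig()
    img = _img(64, 64)
    with pytest.warns(UserWarning, match="donor"):
        out = copy_paste_small(img, [], cfg, np.random.default_rng(0))
    assert len(out.boxes) == len(img.boxes)


def test_copy_paste_increases_counts_and_respects_iou_cap():
    cfg = AugmentConfig(copy_paste_n=(3, 5), max_paste_iou=0.2)
    donors = _donors()
    succeeded = 0
    for trial in range(100):
        img = _img(64, 64)
        out = copy_paste_small(img, donors, cfg,
                               np.random.default_rng(trial))
        added = len(out.boxes) - len(img.boxes)
        out.validate()
        if added:
            succeeded += 1
            pasted = out.boxes[len(img.boxes):]
            ious = box_iou(pasted, out.boxes)
            # a pasted box overlaps every *other* box at most at the cap
            for i in range(len(pasted)):
                row = ious[i].copy()
                row[len(img.boxes) + i] = 0.0     # self
                assert row.max() <= cfg.max_paste_iou + 1e-9
    assert succeeded > 50


# ---------------------------------------------------------------------------
# composed pipeline properties
# ---------------------------------------------------------------------------

def test_pipeline_reproducible_from_seed(small_dataset):
    donors = extract_small_objects(small_dataset)
    outs = []
    for _ in range(2):
        aug = Augmenter(AugmentConfig(seed=9), donor_pool=donors)
        outs.append([aug(img, pool=small_dataset) for img in small_dataset])
    for a, b in zip(*outs):
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.boxes, b.boxes)
        assert np.array_equal(a.labels, b.labels)


def test_boxes_valid_under_many_random_compositions(small_dataset):
    donors = extract_small_objects(small_dataset)
    aug = Augmenter(AugmentConfig(seed=1), donor_pool=donors)
    for i in range(500):
        out = aug(small_dataset[i % len(small_dataset)], pool=small_dataset)
        out.validate(3)
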