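"""Dilation buffers, the size sweep and selection, fusion and rendering."""

import numpy as np
import pytest
from scipy import ndimage

from mscc.buffer import (SweepRow, apply_buffer, fuse, fuse_and_render,
                         make_buffer, select_buffer_size, sweep_buffer_sizes)
from mscc.metrics import evaluate


def test_buffer_size_zero_is_identity(rng):
    mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    np.testing.assert_array_equal(make_buffer(mask, 0).mask, mask)


def test_buffer_negative_size_rejected():
    with pytest.raises(ValueError):
        make_buffer(np.zeros((4, 4), np.uint8), -1)


def test_buffer_single_pixel_radius_two():
    mask = np.zeros((9, 9), np.uint8)
    mask[4, 4] = 1
    buf = make_buffer(mask, 2).mask
    # distance-transform oracle: all pixels within Euclidean distance 2
    rows, cols = np.mgrid[0:9, 0:9]
    want = ((rows - 4) ** 2 + (cols - 4) ** 2 <= 4).astype(np.uint8)
    np.testing.assert_array_equal(buf, want)
    assert buf.sum() == 13


def test_buffer_monotone_and_extensive(rng):
    mask = (rng.random((20, 20)) > 0.9).astype(np.uint8)
    b2 = make_buffer(mask, 2).mask
    b4 = make_buffer(mask, 4).mask
    assert (b2 >= mask).all()
    assert (b4 >= b2).all()


def test_apply_buffer_trivial_and_idempotent(rng):
    patch = (rng.random((12, 12)) > 0.5).astype(np.uint8)
    ones = make_buffer(np.ones((12, 12), np.uint8), 0)
    zeros = make_buffer(np.zeros((12, 12), np.uint8), 0)
    np.testing.assert_array_equal(apply_buffer(patch, ones), patch)
    assert apply_buffer(patch, zeros).sum() == 0
    once = apply_buffer(patch, ones)
    np.testing.assert_array_equal(apply_buffer(once, ones), once)


def test_apply_buffer_removes_outside_components():
    pixel = np.zeros((32, 32), np.uint8)
    pixel[4:10, 4:10] = 1
    patch = pixel.copy()
    patch[24:28, 24:28] = 1  # noise blob far outside the buffer
    buffered = apply_buffer(patch, make_buffer(pixel, 4))
    n_before, _ = ndimage.label(patch)[1], None
    n_after = ndimage.label(buffered)[0].max()
    assert ndimage.label(patch)[1] == 2
    assert n_after == 1
    np.testing.assert_array_equal(buffered, pixel)


def test_sweep_row_count_and_identical_masks(rng):
    masks = [(rng.random((24, 24)) > 0.6).astype(np.uint8) for _ in range(3)]
    gts = [(rng.random((24, 24)) > 0.6).astype(np.uint8) for _ in range(3)]
    rows = sweep_buffer_sizes(masks, masks, gts)
    assert len(rows) == 20
    first = rows[0]
    for r in rows[1:]:  # patch == pixel, so the buffer changes nothing
        assert r.dice == pytest.approx(first.dice)
        assert r.recall == pytest.approx(first.recall)


def test_sweep_recall_non_decreasing(rng):
    pixel = [(rng.random((32, 32)) > 0.8).astype(np.uint8) for _ in range(4)]
    patch = [(rng.random((32, 32)) > 0.5).astype(np.uint8) for _ in range(4)]
    gts = [(rng.random((32, 32)) > 0.7).astype(np.uint8) for _ in range(4)]
    rows = sweep_buffer_sizes(pixel, patch, gts)
    recalls = [r.recall for r in rows]
    assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))


def test_sweep_rejects_empty():
    with pytest.raises(ValueError):
        sweep_buffer_sizes([], [], [])


def _row(size, acc, rec, dice=0.5):
    return SweepRow(size, dice, 0.5, rec, acc, 0.5)


def test_select_interpolated_crossing_rounds_to_grid():
    rows = [_row(s, acc=0.9, rec=0.5) for s in range(2, 24, 2)]
    rows += [_row(24, acc=0.72, rec=0.70), _row(26, acc=0.70, rec=0.72)]
    rows += [_row(s, acc=0.6, rec=0.8) for s in range(28, 42, 2)]
    # diff +0.02 at 24, -0.02 at 26 -> crossing at 25 -> round half-up to 26
    assert select_buffer_size(rows) == 26


def test_select_degenerate_tie_returns_first_size():
    rows = [_row(s, acc=0.8, rec=0.8) for s in range(2, 42, 2)]
    assert select_buffer_size(rows) == 2


def test_select_no_crossing_falls_back_to_dice_max():
    rows = [_row(s, acc=0.9, rec=0.5, dice=0.5 + 0.01 * s)
            for s in range(2, 42, 2)]
    with pytest.warns(UserWarning, match="never intersect"):
        assert select_buffer_size(rows) == 40


def test_fusion_is_union_and_superset(rng):
    a = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    b = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    f = fuse(a, b)
    assert (f >= a).all() and (f >= b).all()
    assert f.sum() == (a.astype(bool) | b.astype(bool)).sum()


def test_fuse_disjoint_masks_add():
    a = np.zeros((8, 8), np.uint8)
    b = np.zeros((8, 8), np.uint8)
    a[:2], b[6:] = 1, 1
    assert fuse(a, b).sum() == a.sum() + b.sum()


def test_overlay_colours_follow_membership_truth_table(rng):
    image = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    pix = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    pat = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    gt = np.zeros((16, 16), np.uint8)
    final, overlay = fuse_and_render(pix, pat, gt, image)
    np.testing.assert_array_equal(final, fuse(pix, pat))
    for r in range(16):
        for c in range(16):
            want = {(1, 0): (255, 0, 0), (0, 1): (0, 255, 0),
                    (1, 1): (255, 255, 0)}.get((pix[r, c], pat[r, c]),
                                               (image[r, c],) * 3)
            assert tuple(overlay[r, c]) == want


def test_overlay_paints_gt_contour_purple():
    image = np.zeros((12, 12), np.uint8)
    gt = np.zeros((12, 12), np.uint8)
    gt[3:9, 3:9] = 1
    empty = np.zeros((12, 12), np.uint8)
    _, overlay = fuse_and_render(empty, empty, gt, image)
    assert tuple(overlay[3, 3]) == (128, 0, 128)   # boundary
    assert tuple(overlay[5, 5]) == (0, 0, 0)       # interior untouched


def test_identical_masks_render_all_yellow(rng):
    m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
    image = np.zeros((10, 10), np.uint8)
    final, overlay = fuse_and_render(m, m, np.zeros_like(m), image)
    np.testing.assert_array_equal(final, m)
    assert (overlay[m.astype(bool)] == (255, 255, 0)).all()
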