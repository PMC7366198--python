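"""Dense-CRF: unary construction, kernel values, exact energies, mean field."""

from itertools import product

import numpy as np
import pytest

from mscc.crf import (CRFParams, GridTooLargeError, PixelFeature,
                      mean_field_refine, pairwise_kernel, refine_mask,
                      total_energy, unary_from_mask)


def brute_force_energy(labels, unary, image, params):
    """Independent per-pair summation oracle (literal double loop)."""
    h, w = labels.shape
    e = 0.0
    for r in range(h):
        for c in range(w):
            e += unary[labels[r, c], r, c]
    flat = [(r, c) for r in range(h) for c in range(w)]
    for i, (r1, c1) in enumerate(flat):
        for r2, c2 in flat[i + 1:]:
            if labels[r1, c1] != labels[r2, c2]:
                e += pairwise_kernel(
                    PixelFeature((r1, c1), float(image[r1, c1])),
                    PixelFeature((r2, c2), float(image[r2, c2])), params)
    return e


def test_unary_costs_from_mask():
    unary = unary_from_mask(np.ones((2, 2), np.uint8), eps=0.1)
    np.testing.assert_allclose(unary[1], -np.log(0.9), rtol=1e-12)
    np.testing.assert_allclose(unary[0], -np.log(0.1), rtol=1e-12)


@pytest.mark.parametrize("eps", [0.0, 0.5, 0.7, -0.1])
def test_unary_eps_domain(eps):
    with pytest.raises(ValueError):
        unary_from_mask(np.zeros((2, 2), np.uint8), eps)


def test_unary_mask_flip_swaps_planes(rng):
    mask = (rng.random((5, 5)) > 0.5).astype(np.uint8)
    a = unary_from_mask(mask, 0.2)
    b = unary_from_mask(1 - mask, 0.2)
    np.testing.assert_array_equal(a[0], b[1])
    np.testing.assert_array_equal(a[1], b[0])


def test_kernel_at_zero_distance_is_weight_sum():
    p = CRFParams(w1=2.5, w2=1.5)
    f = PixelFeature((3, 4), 100.0)
    assert pairwise_kernel(f, f, p) == pytest.approx(4.0)


def test_kernel_hand_value():
    p = CRFParams(w1=1, w2=1, sigma_alpha=1, sigma_beta=1, sigma_gamma=1)
    k = pairwise_kernel(PixelFeature((0, 0), 10.0), PixelFeature((1, 1), 10.0), p)
    assert k == pytest.approx(2 * np.exp(-1.0), rel=1e-12)


def test_kernel_symmetry(rng):
    p = CRFParams()
    for _ in range(20):
        fi = PixelFeature(tuple(rng.integers(0, 50, 2).tolist()),
                          float(rng.integers(0, 256)))
        fj = PixelFeature(tuple(rng.integers(0, 50, 2).tolist()),
                          float(rng.integers(0, 256)))
        assert pairwise_kernel(fi, fj, p) == pytest.approx(
            pairwise_kernel(fj, fi, p), rel=1e-12)


def test_energy_pairwise_off_is_unary_sum(rng):
    p = CRFParams(w1=0, w2=0)
    image = rng.integers(0, 256, (3, 3)).astype(np.uint8)
    mask = (rng.random((3, 3)) > 0.5).astype(np.uint8)
    unary = unary_from_mask(mask, 0.1)
    labels = (rng.random((3, 3)) > 0.5).astype(np.uint8)
    want = unary.reshape(2, -1)[labels.ravel(), np.arange(9)].sum()
    assert total_energy(labels, unary, image, p) == pytest.approx(want)


def test_energy_uniform_labeling_has_zero_pairwise(rng):
    p = CRFParams(w1=3, w2=2, sigma_alpha=5, sigma_beta=5, sigma_gamma=2)
    image = rng.integers(0, 256, (3, 3)).astype(np.uint8)
    unary = unary_from_mask(np.ones((3, 3), np.uint8), 0.1)
    labels = np.ones((3, 3), np.uint8)
    assert total_energy(labels, unary, image, p) \
        == pytest.approx(9 * -np.log(0.9))


def test_energy_matches_brute_force_on_all_2x2_labelings(rng):
    p = CRFParams(w1=1.3, w2=0.7, sigma_alpha=2, sigma_beta=25, sigma_gamma=1)
    image = rng.integers(0, 256, (2, 2)).astype(np.uint8)
    mask = np.array([[1, 0], [0, 1]], np.uint8)
    unary = unary_from_mask(mask, 0.2)
    for bits in product([0, 1], repeat=4):
        labels = np.array(bits, np.uint8).reshape(2, 2)
        assert total_energy(labels, unary, image, p) == pytest.approx(
            brute_force_energy(labels, unary, image, p), rel=1e-10)


def test_energy_refuses_large_grids():
    p = CRFParams()
    big = np.zeros((100, 100), np.uint8)
    with pytest.raises(GridTooLargeError):
        total_energy(big, np.zeros((2, 100, 100)), big, p)


def test_mean_field_zero_iterations_is_unary_argmax(rng):
    mask = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    image = rng.integers(0, 256, (6, 6)).astype(np.uint8)
    p = CRFParams(iterations=0)
    labels, q = mean_field_refine(unary_from_mask(mask, 0.1), image, p)
    np.testing.assert_array_equal(labels, mask)
    np.testing.assert_allclose(q.sum(axis=0), 1.0, rtol=1e-9)


def test_mean_field_zero_weights_keeps_unary_argmax(rng):
    mask = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    image = rng.integers(0, 256, (6, 6)).astype(np.uint8)
    p = CRFParams(w1=0, w2=0, iterations=7)
    labels, _ = mean_field_refine(unary_from_mask(mask, 0.1), image, p)
    np.testing.assert_array_equal(labels, mask)


def test_mean_field_marginals_normalised_every_iteration(rng):
    mask = (rng.random((5, 5)) > 0.5).astype(np.uint8)
    image = rng.integers(0, 256, (5, 5)).astype(np.uint8)
    for it in range(4):
        _, q = mean_field_refine(unary_from_mask(mask, 0.1), image,
                                 CRFParams(iterations=it))
        np.testing.assert_allclose(q.sum(axis=0), 1.0, rtol=1e-9)


def test_mean_field_fills_isolated_hole():
    mask = np.ones((7, 7), np.uint8)
    mask[3, 3] = 0  # wrong-label hole in a uniform region
    image = np.full((7, 7), 100, np.uint8)
    p = CRFParams(w1=0, w2=5, sigma_gamma=2, iterations=3)
    labels, _ = mean_field_refine(unary_from_mask(mask, 0.1), image, p)
    assert labels[3, 3] == 1
    assert labels.sum() == 49


def test_mean_field_label_swap_symmetry(rng):
    mask = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    image = rng.integers(0, 256, (6, 6)).astype(np.uint8)
    p = CRFParams(w1=1, w2=1, sigma_alpha=3, sigma_beta=30, sigma_gamma=1,
                  iterations=5)
    a, _ = mean_field_refine(unary_from_mask(mask, 0.1), image, p)
    b, _ = mean_field_refine(unary_from_mask(1 - mask, 0.1), image, p)
    np.testing.assert_array_equal(a, 1 - b)


def test_mean_field_no_worse_than_unary_when_pairwise_negligible(rng):
    mask = (rng.random((4, 4)) > 0.5).astype(np.uint8)
    image = rng.integers(0, 256, (4, 4)).astype(np.uint8)
    p = CRFParams(w1=5e-7, w2=5e-7, iterations=5)
    unary = unary_from_mask(mask, 0.1)
    labels, _ = mean_field_refine(unary, image, p)
    assert total_energy(labels, unary, image, p) \
        <= total_energy(mask, unary, image, p) + 1e-9


def test_mean_field_rejects_nonfinite_unary():
    u = np.zeros((2, 3, 3))
    u[0, 0, 0] = np.inf
    with pytest.raises(ValueError):
        mean_field_refine(u, np.zeros((3, 3), np.uint8), CRFParams())


def test_windowed_and_exact_paths_agree(rng):
    """The truncated-window message passing matches the dense-matrix path."""
    mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    image = rng.integers(0, 256, (8, 8)).astype(np.uint8)
    base = dict(w1=1.0, w2=0.5, sigma_alpha=1.5, sigma_beta=25.0,
                sigma_gamma=1.0, iterations=4, truncation=12.0)
    exact = CRFParams(exact_threshold=64, **base)
    windowed = CRFParams(exact_threshold=1, **base)
    la, qa = mean_field_refine(unary_from_mask(mask, 0.1), image, exact)
    lb, qb = mean_field_refine(unary_from_mask(mask, 0.1), image, windowed)
    np.testing.assert_array_equal(la, lb)
    np.testing.assert_allclose(qa, qb, atol=1e-8)


def test_energy_trace_csv_is_non_increasing(tmp_path, rng):
    from mscc.crf import write_energy_trace_csv

    mask = (rng.random((5, 5)) > 0.5).astype(np.uint8)
    mask[2, 2] = 1 - mask[2, 1]
    image = np.full((5, 5), 120, np.uint8)
    p = CRFParams(w1=0.5, w2=1.0, sigma_alpha=2, sigma_beta=20,
                  sigma_gamma=1.5, iterations=4)
    write_energy_trace_csv(mask, image, p, tmp_path / "trace.csv")
    lines = (tmp_path / "trace.csv").read_text().splitlines()
    assert lines[0] == "iteration,energy"
    energies = [float(l.split(",")[1]) for l in lines[1:]]
    assert len(energies) == 5
    assert energies[-1] <= energies[0] + 1e-9
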