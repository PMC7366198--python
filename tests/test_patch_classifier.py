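"""Patch classifier: backbones, freezing, prediction, mask reconstruction."""

import numpy as np
import pytest

from mscc.patch_model import (PatchPrediction, PatchTrainConfig,
                              WeightsUnavailableError, build_patch_classifier,
                              predict_patches, reconstruct_mask,
                              train_patch_model)
from mscc.patches import LabeledPatch, PatchGrid, PatchLabel, mesh_patches


def _toy_patches(n, rng, lo_hi=((0, 60), (180, 255))):
    """Separable set: WithoutObject dark patches, WithObject bright ones."""
    out = []
    for i in range(n):
        label = PatchLabel(i % 2)
        lo, hi = lo_hi[label.value]
        px = rng.integers(lo, hi, size=(8, 8)).astype(np.uint8)
        gt = np.full((8, 8), label.value, np.uint8)
        out.append(LabeledPatch(px, gt, label, origin=(0, 0), parent_id=i))
    return out


def test_probabilities_sum_to_one(rng):
    clf = build_patch_classifier(PatchTrainConfig(backbone="tiny-cnn", seed=0))
    probs = clf.predict_proba(rng.integers(0, 255, (5, 8, 8)).astype(np.uint8))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)


def test_pretrained_backbone_raises_without_weights():
    with pytest.raises(WeightsUnavailableError, match="vgg16-random"):
        build_patch_classifier(PatchTrainConfig(backbone="vgg16-pretrained"))


def test_frozen_base_trainable_count_is_dense_head_only():
    cfg = PatchTrainConfig(backbone="vgg16-random", freeze_base=True, seed=0)
    clf = build_patch_classifier(cfg)
    head = (512 * 256 + 256) + (256 * 64 + 64) + (64 * 2 + 2)
    assert sum(p.size for p in clf.trainable_parameters()) == head
    assert sum(p.size for p in clf.base_parameters()) \
        == clf.net.parameter_count() - head


def test_vgg_adapter_shape(rng):
    cfg = PatchTrainConfig(backbone="vgg16-random", freeze_base=True, seed=0)
    clf = build_patch_classifier(cfg)
    x = clf.adapt(rng.integers(0, 255, (2, 8, 8)).astype(np.uint8))
    assert x.shape == (2, 3, 32, 32)
    np.testing.assert_array_equal(x[:, 0], x[:, 1])


def test_tiny_cnn_learns_separable_toy(rng):
    cfg = PatchTrainConfig(backbone="tiny-cnn", learning_rate=3e-3,
                           epochs=8, batch_size=16, seed=0)
    clf = build_patch_classifier(cfg)
    train = _toy_patches(64, rng)
    val = _toy_patches(32, rng)
    clf, hist = train_patch_model(clf, train, val, cfg)
    assert len(hist["train_loss"]) == 8
    assert hist["val_acc"][-1] >= 0.95


def test_frozen_base_is_bit_identical_after_training(rng):
    cfg = PatchTrainConfig(backbone="tiny-cnn", freeze_base=True,
                           learning_rate=1e-3, epochs=2, batch_size=8, seed=0)
    clf = build_patch_classifier(cfg)
    before = [p.data.copy() for p in clf.base_parameters()]
    clf, _ = train_patch_model(clf, _toy_patches(16, rng), [], cfg)
    after = clf.base_parameters()
    assert all(np.array_equal(b, p.data) for b, p in zip(before, after))


def test_training_with_empty_validation_returns_history(rng):
    cfg = PatchTrainConfig(backbone="tiny-cnn", epochs=2, seed=0)
    clf = build_patch_classifier(cfg)
    clf, hist = train_patch_model(clf, _toy_patches(8, rng), [], cfg)
    assert len(hist["train_loss"]) == 2
    assert hist["val_loss"] == []


def test_unbalanced_input_reports_ratio(rng):
    cfg = PatchTrainConfig(backbone="tiny-cnn", epochs=1, seed=0)
    clf = build_patch_classifier(cfg)
    pats = _toy_patches(9, rng)  # 5 without / 4 with
    clf, hist = train_patch_model(clf, pats, [], cfg)
    assert hist["class_ratio"] == pytest.approx(4 / 5)


def test_predictions_order_confidence_and_determinism(rng):
    cfg = PatchTrainConfig(backbone="tiny-cnn", seed=0)
    clf = build_patch_classifier(cfg)
    pats = _toy_patches(10, rng)
    preds1 = predict_patches(clf, pats)
    preds2 = predict_patches(clf, pats)
    assert len(preds1) == 10
    assert [p.parent_id for p in preds1] == list(range(10))
    assert [p.label for p in preds1] == [p.label for p in preds2]
    probs = clf.predict_proba(np.stack([p.pixels for p in pats]))
    for pred, pr in zip(preds1, probs):
        assert pred.label.value == int(pr.argmax())
        assert pred.confidence == pytest.approx(float(pr.max()))


def test_reconstruct_all_with_object():
    grid = PatchGrid(32, 8)
    preds = [PatchPrediction(0, o, PatchLabel.WITH_OBJECT, 1.0)
             for o in grid.origins()]
    assert reconstruct_mask(preds, grid).all()


def test_reconstruct_single_cell_geometry():
    grid = PatchGrid(32, 8)
    preds = [PatchPrediction(0, o,
                             PatchLabel.WITH_OBJECT if o == (8, 16)
                             else PatchLabel.WITHOUT_OBJECT, 1.0)
             for o in grid.origins()]
    mask = reconstruct_mask(preds, grid)
    assert mask.sum() == 64
    assert mask[8:16, 16:24].all()


def test_reconstruct_coverage_errors():
    grid = PatchGrid(16, 8)
    preds = [PatchPrediction(0, (0, 0), PatchLabel.WITH_OBJECT, 1.0)]
    with pytest.raises(ValueError, match="coverage"):
        reconstruct_mask(preds, grid)
    with pytest.raises(ValueError, match="duplicate"):
        reconstruct_mask(preds * 2 + preds, grid)


def test_mesh_label_reconstruct_is_blockwise_majority(small_scene):
    """Labeling GT patches and reconstructing equals strict block majority."""
    grid = PatchGrid(64, 8)
    pats = mesh_patches(small_scene.image, small_scene.gt, grid)
    preds = [PatchPrediction(p.parent_id, p.origin, p.label, 1.0) for p in pats]
    mask = reconstruct_mask(preds, grid)
    blocks = small_scene.gt.reshape(8, 8, 8, 8).swapaxes(1, 2)
    majority = (blocks.sum(axis=(2, 3)) > 32).astype(np.uint8)
    expected = np.kron(majority, np.ones((8, 8), np.uint8))
    np.testing.assert_array_equal(mask, expected)
    n_with = sum(p.label is PatchLabel.WITH_OBJECT for p in pats)
    assert mask.sum() == 64 * n_with


def test_predictions_tsv(tmp_path):
    from mscc.patch_model import write_predictions_tsv

    preds = [PatchPrediction(0, (0, 8), PatchLabel.WITH_OBJECT, 0.75),
             PatchPrediction(0, (8, 0), PatchLabel.WITHOUT_OBJECT, 0.5)]
    write_predictions_tsv(preds, tmp_path / "preds.tsv")
    lines = (tmp_path / "preds.tsv").read_text().splitlines()
    assert len(lines) == 3
    assert lines[1] == "0\t0\t8\tWITH_OBJECT\t0.750000"
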