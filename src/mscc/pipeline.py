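"""End-to-end orchestration of the two-branch segmentation workflow.

Stages (each also exposed as a CLI subcommand):

1. synthesise or load a per-class image/GT dataset;
2. split 1:1:2 per class, eightfold-augment the training images;
3. train the pixel-level network, predict and binarise test masks;
4. refine the pixel masks with the dense CRF;
5. mesh the training images into labeled patches, balance, train the patch
   classifier, predict and reconstruct patch-level test masks;
6. sweep buffer sizes, pick the Accuracy/Recall intersection, apply the
   buffer, fuse the branches, evaluate and render overlays.

Every artefact lands in fixed subfolders of the run directory
(``masks_pixel/``, ``masks_crf/``, ``masks_patch/``, ``masks_final/``,
``overlays/``, ``reports/``).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import buffer as buffer_mod
from . import crf as crf_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import patch_model, patches, pixel_net, synthetic
from .config import RunConfig

log = logging.getLogger("mscc")


@dataclass
class PipelineResult:
    config: RunConfig
    split: io_mod.DatasetSplit
    pixel_history: dict
    patch_history: dict
    pixel_masks: list = field(default_factory=list)
    crf_masks: list = field(default_factory=list)
    patch_masks: list = field(default_factory=list)
    final_masks: list = field(default_factory=list)
    sweep_rows: list = field(default_factory=list)
    buffer_size: int = 0
    records: list = field(default_factory=list)   # (class_id, EvaluationRecord)
    report: metrics_mod.AggregateReport | None = None
    counts: dict = field(default_factory=dict)


def _save_mask_png(mask, path):
    from PIL import Image

    Image.fromarray((np.asarray(mask) * 255).astype(np.uint8), mode="L").save(path)


def run_pipeline(config: RunConfig, scenes=None, out_dir=None) -> PipelineResult:
    """Run every stage in memory; write artefacts only if ``out_dir`` given."""
    t0 = time.time()
    counts = {}
    if scenes is None:
        scenes = synthetic.generate_dataset(
            config.synth.n_classes, config.synth.per_class,
            config.image_edge, config.split_seed)
    split = io_mod.split_dataset(scenes, config.split_ratio, config.split_seed)
    counts["train_images"] = len(split.train)
    counts["val_images"] = len(split.validation)
    counts["test_images"] = len(split.test)
    log.info("split: %d/%d/%d train/val/test",
             *(counts[k] for k in ("train_images", "val_images", "test_images")))

    # -- pixel branch ------------------------------------------------------
    aug_pairs = patches.augment_eightfold(
        [(img, gt) for img, gt, _ in split.train])
    counts["augmented_train_images"] = len(aug_pairs)
    net, n_params = pixel_net.build_network(config.network,
                                            seed=config.pixel_train.seed)
    counts["pixel_parameters"] = n_params
    log.info("pixel network %s: %d parameters", config.network.variant, n_params)
    net, pixel_history = pixel_net.train_pixel_model(
        net, aug_pairs, [(i, g) for i, g, _ in split.validation],
        config.pixel_train)
    log.info("pixel training done (%.1fs)", time.time() - t0)

    pixel_masks, crf_masks = [], []
    for img, _, _ in split.test:
        _, mask = pixel_net.predict_mask(net, img, config.prediction_threshold)
        pixel_masks.append(mask)
        crf_masks.append(crf_mod.refine_mask(mask, img, config.crf))
    log.info("pixel prediction + CRF done (%.1fs)", time.time() - t0)

    # -- patch branch ------------------------------------------------------
    grid = patches.PatchGrid(config.image_edge, config.patch_edge)
    train_patches = []
    for pid, (img, gt, _) in enumerate(split.train):
        train_patches.extend(patches.mesh_patches(
            img, gt, grid, config.criterion_fraction, parent_id=pid))
    counts["train_patches"] = len(train_patches)
    label_counts = patches.count_labels(train_patches)
    counts["with_object_patches"] = label_counts[patches.PatchLabel.WITH_OBJECT]
    counts["without_object_patches"] = label_counts[patches.PatchLabel.WITHOUT_OBJECT]
    balanced = patches.balance_patches(train_patches,
                                       seed=config.patch_train.seed)
    counts["balanced_patches"] = len(balanced)
    val_patches = []
    for pid, (img, gt, _) in enumerate(split.validation):
        val_patches.extend(patches.mesh_patches(
            img, gt, grid, config.criterion_fraction, parent_id=pid))
    clf = patch_model.build_patch_classifier(config.patch_train)
    clf, patch_history = patch_model.train_patch_model(
        clf, balanced, val_patches, config.patch_train)
    log.info("patch training done (%.1fs)", time.time() - t0)

    patch_masks = []
    for pid, (img, gt, _) in enumerate(split.test):
        test_patches = patches.mesh_patches(img, gt, grid,
                                            config.criterion_fraction,
                                            parent_id=pid)
        preds = patch_model.predict_patches(clf, test_patches)
        patch_masks.append(patch_model.reconstruct_mask(preds, grid))
    log.info("patch prediction done (%.1fs)", time.time() - t0)

    # -- buffer sweep, fusion, evaluation ---------------------------------
    gts = [gt for _, gt, _ in split.test]
    sweep_rows = buffer_mod.sweep_buffer_sizes(crf_masks, patch_masks, gts,
                                               config.buffer_sizes)
    size = buffer_mod.select_buffer_size(sweep_rows)
    log.info("selected buffer size: %d", size)

    final_masks, records, overlays = [], [], []
    for (img, gt, cid), pm, qm in zip(split.test, crf_masks, patch_masks):
        buffered = buffer_mod.apply_buffer(qm, buffer_mod.make_buffer(pm, size))
        final, overlay = buffer_mod.fuse_and_render(pm, buffered, gt, img)
        final_masks.append(final)
        overlays.append(overlay)
        records.append((cid, metrics_mod.evaluate(final, gt)))
    report = metrics_mod.aggregate(records)
    log.info("fused Dice %.4f over %d test scenes (%.1fs total)",
             report.overall.dice, len(records), time.time() - t0)

    result = PipelineResult(
        config=config, split=split, pixel_history=pixel_history,
        patch_history=patch_history, pixel_masks=pixel_masks,
        crf_masks=crf_masks, patch_masks=patch_masks,
        final_masks=final_masks, sweep_rows=sweep_rows, buffer_size=size,
        records=records, report=report, counts=counts)

    if out_dir is not None:
        _write_artefacts(result, overlays, Path(out_dir))
    return result


def _write_artefacts(result: PipelineResult, overlays, out: Path):
    from PIL import Image

    for sub in ("masks_pixel", "masks_crf", "masks_patch", "masks_final",
                "overlays", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for i, (pm, cm, qm, fm, ov) in enumerate(zip(
            result.pixel_masks, result.crf_masks, result.patch_masks,
            result.final_masks, overlays)):
        _save_mask_png(pm, out / "masks_pixel" / f"{i:03d}.png")
        _save_mask_png(cm, out / "masks_crf" / f"{i:03d}.png")
        _save_mask_png(qm, out / "masks_patch" / f"{i:03d}.png")
        _save_mask_png(fm, out / "masks_final" / f"{i:03d}.png")
        Image.fromarray(ov, mode="RGB").save(out / "overlays" / f"{i:03d}.png")
    buffer_mod.write_sweep_csv(result.sweep_rows,
                               out / "reports" / "buffer_sweep.csv")
    pixel_net.save_history_csv(result.pixel_history,
                               out / "reports" / "pixel_history.csv")
    metrics_mod.write_records_csv(
        [(f"{i:03d}.png", cid, rec) for i, (cid, rec)
         in enumerate(result.records)], out / "reports" / "per_image.csv")
    metrics_mod.write_aggregate_csv(result.report,
                                    out / "reports" / "aggregate.csv")
    result.config.save(out / "reports" / "config.yaml")
    with open(out / "reports" / "run_log.txt", "w") as fh:
        fh.write(f"config_hash\t{result.config.config_hash()}\n")
        fh.write(f"buffer_size\t{result.buffer_size}\n")
        for k, v in result.counts.items():
            fh.write(f"{k}\t{v}\n")
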