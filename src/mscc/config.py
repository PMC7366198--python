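"""Run configuration: one object holding every stage's settings.

Defaults follow the reference working point of the method: 256-pixel images,
8-pixel patches, strict-majority (0.5) patch labeling, a 1:1:2 per-class
split, binary cross-entropy / Adam at 1.5e-4 for 50 epochs on the pixel
network, categorical cross-entropy / Adam at 1.0e-4 for 15 epochs on the
patch classifier, and a buffer sweep over even sizes 2..40.

:meth:`RunConfig.test_profile` is a reduced working point (64-pixel scenes,
halved filter schedule, the tiny-cnn patch backbone, short schedules and a
narrow CRF window) sized for desk-scale CPU runs; its training rates are
scaled up to suit the short schedules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .crf import CRFParams
from .patch_model import PatchTrainConfig
from .pixel_net import DEFAULT_LEVEL_FILTERS, NetworkSpec, TrainConfig


@dataclass
class SynthConfig:
    n_classes: int = 21
    per_class: int = 20


@dataclass
class RunConfig:
    dataset_root: str = "dataset"
    output_dir: str = "runs/default"
    image_edge: int = 256
    patch_edge: int = 8
    criterion_fraction: float = 0.5
    split_seed: int = 0
    split_ratio: tuple = (1, 1, 2)
    prediction_threshold: float = 0.5
    buffer_sizes: tuple = tuple(range(2, 41, 2))
    synth: SynthConfig = field(default_factory=SynthConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    pixel_train: TrainConfig = field(default_factory=TrainConfig)
    patch_train: PatchTrainConfig = field(default_factory=PatchTrainConfig)
    crf: CRFParams = field(default_factory=CRFParams)

    @classmethod
    def test_profile(cls, seed: int = 0) -> "RunConfig":
        """Reduced working point for CPU-scale end-to-end runs."""
        return cls(
            image_edge=64,
            synth=SynthConfig(n_classes=3, per_class=16),
            split_seed=seed,
            network=NetworkSpec(variant="B3",
                                level_filters=tuple(n // 2 for n in
                                                    DEFAULT_LEVEL_FILTERS)),
            pixel_train=TrainConfig(learning_rate=1e-3, epochs=10,
                                    batch_size=4, seed=seed),
            patch_train=PatchTrainConfig(backbone="tiny-cnn",
                                         learning_rate=3e-3, epochs=5,
                                         batch_size=64, seed=seed),
            crf=CRFParams(w1=1.0, w2=0.5, sigma_alpha=2.0, sigma_beta=15.0,
                          sigma_gamma=1.0, iterations=5, truncation=3.0),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            dataset_root=raw["dataset_root"],
            output_dir=raw["output_dir"],
            image_edge=raw["image_edge"],
            patch_edge=raw["patch_edge"],
            criterion_fraction=raw["criterion_fraction"],
            split_seed=raw["split_seed"],
            split_ratio=tuple(raw["split_ratio"]),
            prediction_threshold=raw["prediction_threshold"],
            buffer_sizes=tuple(raw["buffer_sizes"]),
            synth=SynthConfig(**raw["synth"]),
            network=NetworkSpec(variant=raw["network"]["variant"],
                                level_filters=tuple(raw["network"]["level_filters"])),
            pixel_train=TrainConfig(**raw["pixel_train"]),
            patch_train=PatchTrainConfig(**raw["patch_train"]),
            crf=CRFParams(**raw["crf"]),
        )

    def with_seed(self, seed: int) -> "RunConfig":
        """Rewire every stage seed from one master seed."""
        return replace(
            self, split_seed=seed,
            pixel_train=replace(self.pixel_train, seed=seed + 1),
            patch_train=replace(self.patch_train, seed=seed + 2))
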