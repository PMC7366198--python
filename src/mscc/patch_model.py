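"""Patch-level segmentation: classify 8x8 tiles, reassemble a coarse mask.

A classifier assigns each patch *WithObject* / *WithoutObject*; the predicted
labels are painted back onto the patch grid to form a block-wise mask.  Three
backbones are available:

* ``tiny-cnn`` — a two-stage convolutional network that accepts 8x8 patches
  directly; trains in seconds on a CPU and is the default everywhere.
* ``vgg16-random`` — the VGG-16 topology (13 convolutions, 5 poolings) with
  randomly initialised, frozen convolutional weights and a trainable dense
  head; exercises the frozen-base fine-tuning path without any weight file.
* ``vgg16-pretrained`` — same topology with ImageNet weights; building it
  raises :class:`WeightsUnavailableError` unless a weight file is supplied,
  with the fallback backbones named in the message.

Patches enter the VGG backbones through an input adapter that replicates the
grayscale channel three times and upscales 8x8 to 32x32 by nearest neighbour
(the smallest input the five pooling stages admit).  With a frozen base only
the dense head (flatten -> 256 -> 64 -> 2 soft-max) is trained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .patches import LabeledPatch, PatchGrid, PatchLabel

BACKBONES = ("tiny-cnn", "vgg16-random", "vgg16-pretrained")

VGG16_CONV_PLAN = ((64, 64), (128, 128), (256, 256, 256),
                   (512, 512, 512), (512, 512, 512))


class WeightsUnavailableError(RuntimeError):
    pass


@dataclass
class PatchTrainConfig:
    backbone: str = "tiny-cnn"
    learning_rate: float = 1.0e-4
    epochs: int = 15
    batch_size: int = 32
    freeze_base: bool = False
    channel_replication: int = 3
    upscale_factor: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.backbone == "vgg16-pretrained":
            self.freeze_base = True


@dataclass
class PatchPrediction:
    parent_id: int
    origin: tuple[int, int]
    label: PatchLabel
    confidence: float  # soft-max probability of the predicted label


class TinyCNN(nn.Module):
    """conv(8) -> pool -> conv(16) -> pool -> dense 32 -> 2 logits; 8x8 input."""

    def __init__(self, rng):
        super().__init__()
        self.c1 = nn.ConvBNReLU(1, 8, 3, rng)
        self.c2 = nn.ConvBNReLU(8, 16, 3, rng)
        self.fc1 = nn.Linear(16 * 2 * 2, 32, rng)
        self.fc2 = nn.Linear(32, 2, rng)

    def forward(self, x):
        x = nn.maxpool2x2(self.c1(x))
        x = nn.maxpool2x2(self.c2(x))
        x = nn.relu(self.fc1(nn.reshape(x, (x.shape[0], -1))))
        return self.fc2(x)

    base_modules = ("c1", "c2")


class VGG16(nn.Module):
    """VGG-16 topology for 32x32 3-channel input, two-way dense head."""

    def __init__(self, rng):
        super().__init__()
        layers, cin = [], 3
        for stage in VGG16_CONV_PLAN:
            for cout in stage:
                layers.append(nn.ConvBNReLU(cin, cout, 3, rng))
                cin = cout
            layers.append(nn.MaxPool2x2())
        self.base = nn.Sequential(*layers)
        self.fc1 = nn.Linear(512, 256, rng)
        self.fc2 = nn.Linear(256, 64, rng)
        self.fc3 = nn.Linear(64, 2, rng)

    def forward(self, x):
        x = self.base(x)  # (N, 512, 1, 1)
        x = nn.reshape(x, (x.shape[0], -1))
        x = nn.relu(self.fc1(x))
        x = nn.relu(self.fc2(x))
        return self.fc3(x)


@dataclass
class PatchClassifier:
    net: nn.Module
    config: PatchTrainConfig
    head_names: tuple = ("fc1", "fc2", "fc3")

    def adapt(self, patches: np.ndarray) -> np.ndarray:
        """uint8 (N, e, e) patches -> network input on [0, 1]."""
        x = np.asarray(patches, dtype=np.float32) / 255.0
        if self.config.backbone == "tiny-cnn":
            return x[:, None]
        f = self.config.upscale_factor
        x = x.repeat(f, axis=1).repeat(f, axis=2)  # nearest-neighbour upscale
        return np.broadcast_to(
            x[:, None], (x.shape[0], self.config.channel_replication,
                         x.shape[1], x.shape[2])).copy()

    def trainable_parameters(self):
        if not self.config.freeze_base:
            return self.net.parameters()
        head = []
        for name in self.head_names:
            head.extend(getattr(self.net, name).parameters())
        return head

    def base_parameters(self):
        trainable = {id(p) for p in self.trainable_parameters()}
        return [p for p in self.net.parameters() if id(p) not in trainable]

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        self.net.eval()
        x = self.adapt(patches)
        out = []
        for lo in range(0, len(x), 256):
            logits = self.net(Tensor(x[lo:lo + 256]))
            out.append(nn.softmax(Tensor(logits.data)).data)
        return np.concatenate(out, axis=0)


def build_patch_classifier(config: PatchTrainConfig,
                           pretrained_weights=None) -> PatchClassifier:
    """Build a classifier; output probabilities always sum to 1 per patch."""
    rng = np.random.default_rng(config.seed)
    if config.backbone == "tiny-cnn":
        clf = PatchClassifier(TinyCNN(rng), config, head_names=("fc1", "fc2"))
    elif config.backbone == "vgg16-random":
        clf = PatchClassifier(VGG16(rng), config)
    else:
        if pretrained_weights is None:
            raise WeightsUnavailableError(
                "pretrained VGG-16 weights are not available offline; pass a "
                "weight file, or use backbone 'vgg16-random' (frozen random "
                "base) or 'tiny-cnn'")
        clf = PatchClassifier(VGG16(rng), config)
        clf.net.load_state_dict(dict(np.load(pretrained_weights)))
    return clf


def train_patch_model(classifier: PatchClassifier,
                      balanced_patches: list[LabeledPatch],
                      val_patches: list[LabeledPatch],
                      config: PatchTrainConfig):
    """Fine-tune on labeled patches with Adam + categorical cross-entropy.

    Warns (via the returned history's ``class_ratio``) when the input is not
    balanced, but proceeds.  Returns the classifier and per-epoch history.
    """
    labels = np.array([p.label.value for p in balanced_patches])
    n_with = int((labels == 1).sum())
    ratio = n_with / max(1, len(labels) - n_with)
    x = classifier.adapt(np.stack([p.pixels for p in balanced_patches]))
    xv = (classifier.adapt(np.stack([p.pixels for p in val_patches]))
          if val_patches else None)
    yv = (np.array([p.label.value for p in val_patches])
          if val_patches else None)

    params = classifier.trainable_parameters()
    frozen_before = [p.data.copy() for p in classifier.base_parameters()]
    opt = nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "train_acc": [], "val_loss": [],
               "val_acc": [], "class_ratio": ratio}
    for _ in range(config.epochs):
        classifier.net.train()
        if config.freeze_base:
            _set_base_eval(classifier)
        order = rng.permutation(len(x))
        losses, accs = [], []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            logits = classifier.net(Tensor(x[idx]))
            loss = nn.softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            accs.append(float((logits.data.argmax(1) == labels[idx]).mean()))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(float(np.mean(accs)))
        if xv is not None and len(xv):
            classifier.net.eval()
            logits = _batched_logits(classifier.net, xv)
            history["val_loss"].append(
                float(nn.softmax_cross_entropy(Tensor(logits), yv).data))
            history["val_acc"].append(float((logits.argmax(1) == yv).mean()))
    classifier.net.eval()
    if config.freeze_base:
        for before, p in zip(frozen_before, classifier.base_parameters()):
            if not np.array_equal(before, p.data):
                raise AssertionError("frozen base parameters changed")
    return classifier, history


def _set_base_eval(classifier):
    # frozen base: keep its batch-norm statistics fixed as well
    for name in vars(classifier.net).get("_modules", {}):
        if name not in classifier.head_names:
            classifier.net._modules[name].eval()


def _batched_logits(net, x, batch=256):
    return np.concatenate([net(Tensor(x[lo:lo + batch])).data
                           for lo in range(0, len(x), batch)])


def predict_patches(classifier: PatchClassifier,
                    patches: list[LabeledPatch]) -> list[PatchPrediction]:
    """One prediction per patch, order preserving, deterministic in eval mode."""
    probs = classifier.predict_proba(np.stack([p.pixels for p in patches]))
    out = []
    for p, pr in zip(patches, probs):
        k = int(pr.argmax())
        out.append(PatchPrediction(parent_id=p.parent_id, origin=p.origin,
                                   label=PatchLabel(k), confidence=float(pr[k])))
    return out


def write_predictions_tsv(predictions: list[PatchPrediction], path) -> None:
    """Tab-separated predictions: parent_id, row, col, label, confidence."""
    with open(path, "w") as fh:
        fh.write("parent_id\trow\tcol\tlabel\tconfidence\n")
        for p in predictions:
            fh.write(f"{p.parent_id}\t{p.origin[0]}\t{p.origin[1]}\t"
                     f"{p.label.name}\t{p.confidence:.6f}\n")


def reconstruct_mask(predictions: list[PatchPrediction],
                     grid: PatchGrid) -> np.ndarray:
    """Fill each 8x8 cell with its predicted label; exact coverage required."""
    seen = {}
    for p in predictions:
        if p.origin in seen:
            raise ValueError(f"duplicate patch prediction at origin {p.origin}")
        seen[p.origin] = p
    missing = [o for o in grid.origins() if o not in seen]
    extra = [o for o in seen if o not in set(grid.origins())]
    if missing or extra:
        raise ValueError(f"patch coverage error; missing={missing[:5]} "
                         f"extra={extra[:5]}")
    e = grid.patch_edge
    mask = np.zeros((grid.image_edge, grid.image_edge), dtype=np.uint8)
    for (r0, c0), p in seen.items():
        mask[r0:r0 + e, c0:c0 + e] = p.label.value
    return mask
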