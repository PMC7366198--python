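"""U-Net and the multi-receptive-field block variants, with training.

The encoder-decoder has 9 blocks (4 encoder, 1 bottleneck, 4 decoder) joined
by skip connections; 2x2 max pooling downsamples, 2x2 transposed convolution
upsamples, and the head is a 1x1 convolution producing per-pixel foreground
logits (probabilities after the logistic).  Every convolution and transposed
convolution is followed by batch normalisation and ReLU.

Block variants (``filters`` is the per-branch filter count N per level; every
block concatenates four taps so its output carries 4N channels, which makes
the plain baseline's channel schedule [64, 128, 256, 512, 1024] the 4N of
N = [16, 32, 64, 128, 256]):

* ``PLAIN`` — two successive 3x3 convolutions at 4N filters each (the
  classical U-Net block).
* ``B1`` — four parallel branches of 1x1, 3x3, 5x5 and 7x7 convolutions,
  N filters each, concatenated; widens the receptive field directly, at the
  price of more parameters.
* ``B2`` — the 5x5 and 7x7 branches are replaced by one shared stack of
  three successive 3x3 convolutions; the outputs after the first, second and
  third stage (receptive fields 3, 5, 7) are concatenated with a parallel
  1x1 branch.
* ``B3`` — as B2 but every 3x3 is factorised into a 3x1 followed by a 1x3
  convolution, which further cuts parameters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

VARIANTS = ("PLAIN", "B1", "B2", "B3")
DEFAULT_LEVEL_FILTERS = (16, 32, 64, 128, 256)


@dataclass(frozen=True)
class BlockSpec:
    variant: str
    filters: int  # per-branch filter count N

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; pick from {VARIANTS}")

    @property
    def out_channels(self) -> int:
        return 4 * self.filters


@dataclass(frozen=True)
class NetworkSpec:
    """Variant plus the per-level branch-filter schedule (encoder order).

    Levels 1-4 are the encoder, level 5 the bottleneck; decoder blocks mirror
    the encoder schedule in reverse so paired blocks (1&9, 2&8, 3&7, 4&6)
    carry the same filter count.
    """

    variant: str = "B3"
    level_filters: tuple = DEFAULT_LEVEL_FILTERS

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; pick from {VARIANTS}")
        if len(self.level_filters) != 5:
            raise ValueError("level_filters must list 5 levels")


@dataclass
class TrainConfig:
    learning_rate: float = 1.5e-4
    epochs: int = 50
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class _Block(nn.Module):
    def __init__(self, spec: BlockSpec, cin: int, rng, dtype=np.float32):
        super().__init__()
        n = spec.filters
        self.variant = spec.variant
        if spec.variant == "PLAIN":
            self.conv1 = nn.ConvBNReLU(cin, 4 * n, 3, rng, dtype)
            self.conv2 = nn.ConvBNReLU(4 * n, 4 * n, 3, rng, dtype)
        elif spec.variant == "B1":
            self.b1x1 = nn.ConvBNReLU(cin, n, 1, rng, dtype)
            self.b3x3 = nn.ConvBNReLU(cin, n, 3, rng, dtype)
            self.b5x5 = nn.ConvBNReLU(cin, n, 5, rng, dtype)
            self.b7x7 = nn.ConvBNReLU(cin, n, 7, rng, dtype)
        else:
            self.b1x1 = nn.ConvBNReLU(cin, n, 1, rng, dtype)
            if spec.variant == "B2":
                self.s1 = nn.ConvBNReLU(cin, n, 3, rng, dtype)
                self.s2 = nn.ConvBNReLU(n, n, 3, rng, dtype)
                self.s3 = nn.ConvBNReLU(n, n, 3, rng, dtype)
            else:  # B3: each 3x3 factorised into 3x1 then 1x3
                self.s1 = nn.Sequential(nn.ConvBNReLU(cin, n, (3, 1), rng, dtype),
                                        nn.ConvBNReLU(n, n, (1, 3), rng, dtype))
                self.s2 = nn.Sequential(nn.ConvBNReLU(n, n, (3, 1), rng, dtype),
                                        nn.ConvBNReLU(n, n, (1, 3), rng, dtype))
                self.s3 = nn.Sequential(nn.ConvBNReLU(n, n, (3, 1), rng, dtype),
                                        nn.ConvBNReLU(n, n, (1, 3), rng, dtype))

    def forward(self, x):
        if self.variant == "PLAIN":
            return self.conv2(self.conv1(x))
        if self.variant == "B1":
            return nn.concat([self.b3x3(x), self.b5x5(x), self.b7x7(x),
                              self.b1x1(x)], axis=1)
        t1 = self.s1(x)
        t2 = self.s2(t1)
        t3 = self.s3(t2)
        return nn.concat([t1, t2, t3, self.b1x1(x)], axis=1)


class _UpBNReLU(nn.Module):
    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, cout, rng, dtype)
        self.bn = nn.BatchNorm2d(cout, dtype)

    def forward(self, x):
        return nn.relu(self.bn(self.up(x)))


class SegmentationNet(nn.Module):
    """The 9-block encoder-decoder for any block variant.

    Input ``(N, 1, H, W)`` with H, W divisible by 16; output per-pixel
    foreground logits of the same spatial shape.
    """

    def __init__(self, spec: NetworkSpec, rng=None, dtype=np.float32):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.spec = spec
        f = list(spec.level_filters)
        ch = [4 * n for n in f]  # per-level block output channels
        self.enc1 = _Block(BlockSpec(spec.variant, f[0]), 1, rng, dtype)
        self.enc2 = _Block(BlockSpec(spec.variant, f[1]), ch[0], rng, dtype)
        self.enc3 = _Block(BlockSpec(spec.variant, f[2]), ch[1], rng, dtype)
        self.enc4 = _Block(BlockSpec(spec.variant, f[3]), ch[2], rng, dtype)
        self.bottleneck = _Block(BlockSpec(spec.variant, f[4]), ch[3], rng, dtype)
        self.up4 = _UpBNReLU(ch[4], ch[3], rng, dtype)
        self.dec4 = _Block(BlockSpec(spec.variant, f[3]), 2 * ch[3], rng, dtype)
        self.up3 = _UpBNReLU(ch[3], ch[2], rng, dtype)
        self.dec3 = _Block(BlockSpec(spec.variant, f[2]), 2 * ch[2], rng, dtype)
        self.up2 = _UpBNReLU(ch[2], ch[1], rng, dtype)
        self.dec2 = _Block(BlockSpec(spec.variant, f[1]), 2 * ch[1], rng, dtype)
        self.up1 = _UpBNReLU(ch[1], ch[0], rng, dtype)
        self.dec1 = _Block(BlockSpec(spec.variant, f[0]), 2 * ch[0], rng, dtype)
        self.head = nn.Conv2d(ch[0], 1, 1, rng, dtype)

    def forward(self, x):
        pool = nn.maxpool2x2
        e1 = self.enc1(x)
        e2 = self.enc2(pool(e1))
        e3 = self.enc3(pool(e2))
        e4 = self.enc4(pool(e3))
        b = self.bottleneck(pool(e4))
        d4 = self.dec4(nn.concat([self.up4(b), e4]))
        d3 = self.dec3(nn.concat([self.up3(d4), e3]))
        d2 = self.dec2(nn.concat([self.up2(d3), e2]))
        d1 = self.dec1(nn.concat([self.up1(d2), e1]))
        return self.head(d1)


def build_network(spec: NetworkSpec, seed: int = 0,
                  dtype=np.float32) -> tuple[SegmentationNet, int]:
    """Build a network and report its exact trainable parameter count."""
    rng = np.random.default_rng(seed)
    net = SegmentationNet(spec, rng, dtype)
    return net, net.parameter_count()


def block_parameter_count(spec: BlockSpec, cin: int) -> int:
    """Closed-form trainable parameter count of a single block.

    Counts convolution weights and biases plus the batch-norm scale and shift
    of every convolution stage; used as an independent cross-check of the
    built networks.
    """
    n = spec.filters

    def conv(ci, co, kh, kw):
        return co * ci * kh * kw + co + 2 * co  # weights + bias + BN (gamma, beta)

    if spec.variant == "PLAIN":
        return conv(cin, 4 * n, 3, 3) + conv(4 * n, 4 * n, 3, 3)
    if spec.variant == "B1":
        return (conv(cin, n, 1, 1) + conv(cin, n, 3, 3)
                + conv(cin, n, 5, 5) + conv(cin, n, 7, 7))
    if spec.variant == "B2":
        return (conv(cin, n, 1, 1) + conv(cin, n, 3, 3)
                + conv(n, n, 3, 3) + conv(n, n, 3, 3))
    # B3
    pair = lambda ci: conv(ci, n, 3, 1) + conv(n, n, 1, 3)
    return conv(cin, n, 1, 1) + pair(cin) + pair(n) + pair(n)


# -- training and prediction ------------------------------------------------

def _as_batches(images: np.ndarray, masks: np.ndarray, batch_size: int, order):
    for lo in range(0, len(order), batch_size):
        idx = order[lo:lo + batch_size]
        yield images[idx], masks[idx]


def _prepare(pairs) -> tuple[np.ndarray, np.ndarray]:
    """(image, mask[, ...]) pairs -> float32 (N,1,H,W) arrays on [0,1]."""
    imgs = np.stack([np.asarray(p[0], dtype=np.float32) / 255.0 for p in pairs])
    gts = np.stack([np.asarray(p[1], dtype=np.float32) for p in pairs])
    return imgs[:, None], gts[:, None]


def train_pixel_model(network: SegmentationNet, train_set, val_set,
                      config: TrainConfig):
    """Minimise mean binary cross-entropy with Adam.

    ``train_set``/``val_set`` are lists of ``(image, gt, ...)`` with uint8
    images and binary masks.  Returns the trained network and a history dict
    with per-epoch train/validation loss and pixel accuracy.
    """
    if not train_set:
        raise ValueError("empty training set")
    x_tr, y_tr = _prepare(train_set)
    x_va, y_va = _prepare(val_set) if val_set else (None, None)
    opt = nn.Adam(network.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc")}
    for _ in range(config.epochs):
        network.train()
        order = rng.permutation(len(x_tr))
        losses, accs = [], []
        for xb, yb in _as_batches(x_tr, y_tr, config.batch_size, order):
            logits = network(Tensor(xb))
            loss = nn.bce_with_logits(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            accs.append(float(((logits.data > 0) == (yb > 0.5)).mean()))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(float(np.mean(accs)))
        if x_va is not None:
            vl, va = _evaluate_loss_acc(network, x_va, y_va, config.batch_size)
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
    network.eval()
    return network, history


def _evaluate_loss_acc(network, x, y, batch_size):
    network.eval()
    losses, accs = [], []
    for lo in range(0, len(x), batch_size):
        xb, yb = x[lo:lo + batch_size], y[lo:lo + batch_size]
        logits = network(Tensor(xb))
        losses.append(float(nn.bce_with_logits(logits, yb).data))
        accs.append(float(((logits.data > 0) == (yb > 0.5)).mean()))
    return float(np.mean(losses)), float(np.mean(accs))


def predict_mask(network: SegmentationNet, image: np.ndarray,
                 threshold: float = 0.5):
    """Per-pixel foreground probabilities and the strict-threshold mask."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("predict_mask expects a single 2-D grayscale image")
    if image.shape[0] % 16 or image.shape[1] % 16:
        raise ValueError("image edges must be divisible by 16")
    network.eval()
    x = image.astype(np.float32)[None, None] / 255.0
    logits = network(Tensor(x)).data[0, 0]
    probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    return probs, (probs > threshold).astype(np.uint8)


def save_history_csv(history: dict, path) -> None:
    path = Path(path)
    epochs = len(history["train_loss"])
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
        for i in range(epochs):
            w.writerow([i + 1, history["train_loss"][i], history["train_acc"][i],
                        history["val_loss"][i] if history["val_loss"] else "",
                        history["val_acc"][i] if history["val_acc"] else ""])


def save_checkpoint(network: SegmentationNet, path) -> None:
    np.savez_compressed(path, **network.state_dict())


def load_checkpoint(network: SegmentationNet, path) -> SegmentationNet:
    with np.load(path) as data:
        network.load_state_dict({k: data[k] for k in data.files})
    return network
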