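"""Dataset loading, standardisation, and the 1:1:2 per-class split.

Images are standardised to single-channel 8-bit grids of a fixed square edge
(256 by default).  Grayscale conversion uses ITU-R 601 luma weights with
round-half-up; images are resized bilinearly while masks use nearest
neighbour and are re-binarised, which keeps them strictly {0, 1}.
Coordinates are row-major, 0-based ``(row, col)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

DEFAULT_EDGE = 256

#: ITU-R 601 luma weights (R, G, B)
LUMA = (0.299, 0.587, 0.114)


@dataclass
class DatasetSplit:
    """Per-class 1:1:2 partition into train / validation / test.

    Each entry is ``(image, gt, class_id)``.  With ``n`` scenes in a class,
    train and validation each receive ``floor(n/4)`` scenes and the test set
    takes the remainder, so the test set is always the largest.
    """

    train: list
    validation: list
    test: list


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a raster to a single-channel uint8 grid.

    1-channel input passes through unchanged; 3-channel input is combined
    with ITU-R 601 weights and rounded half-up.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] == 3:
        y = (LUMA[0] * arr[..., 0] + LUMA[1] * arr[..., 1]
             + LUMA[2] * arr[..., 2])
        return np.floor(y + 0.5).astype(np.uint8)
    raise ValueError(f"expected 1- or 3-channel raster, got shape {arr.shape}")


def _resize(arr: np.ndarray, edge: int, nearest: bool) -> np.ndarray:
    if arr.shape == (edge, edge):
        return arr
    img = Image.fromarray(arr)
    method = Image.NEAREST if nearest else Image.BILINEAR
    return np.asarray(img.resize((edge, edge), method))


def load_pair(image_path, gt_path, edge: int = DEFAULT_EDGE):
    """Load an image/GT pair, standardised to ``edge x edge``.

    The GT is binarised (any nonzero value becomes foreground 1).
    """
    try:
        img = np.asarray(Image.open(image_path).convert("RGB"))
        gt = np.asarray(Image.open(gt_path).convert("L"))
    except OSError as exc:
        raise OSError(f"unreadable raster: {exc}") from exc
    gray = _resize(to_grayscale(img), edge, nearest=False)
    mask = (_resize(gt, edge, nearest=True) > 0).astype(np.uint8)
    if gray.shape != mask.shape:
        raise ValueError("image/GT shape mismatch after standardisation")
    return gray, mask


def load_dataset(root, edge: int = DEFAULT_EDGE) -> list:
    """Load a ``<class>/<idx>.png`` + ``<class>/<idx>_gt.png`` tree.

    Returns ``(image, gt, class_id)`` triples sorted by class then index.
    """
    root = Path(root)
    triples = []
    for cdir in sorted(p for p in root.iterdir() if p.is_dir()):
        class_id = int(cdir.name)
        for ipath in sorted(cdir.glob("*.png")):
            if ipath.stem.endswith("_gt"):
                continue
            gpath = ipath.with_name(ipath.stem + "_gt.png")
            if not gpath.exists():
                raise FileNotFoundError(f"missing GT for {ipath}")
            img, gt = load_pair(ipath, gpath, edge)
            triples.append((img, gt, class_id))
    if not triples:
        raise FileNotFoundError(f"no image/GT pairs under {root}")
    return triples


def split_dataset(scenes, ratio=(1, 1, 2), seed: int = 0) -> DatasetSplit:
    """Randomly split per class in the given ratio (default 1:1:2).

    ``scenes`` is a list of ``(image, gt, class_id)`` triples (objects with
    ``.image``/``.gt``/``.class_id`` attributes are also accepted).  Shuffling
    is driven by ``seed``; the three sets are disjoint and their union is the
    input.
    """
    if tuple(ratio) != (1, 1, 2):
        raise ValueError("only the 1:1:2 split ratio is supported")

    def _triple(s):
        if isinstance(s, tuple):
            return s
        return (s.image, s.gt, s.class_id)

    by_class: dict[int, list] = {}
    for s in scenes:
        t = _triple(s)
        by_class.setdefault(t[2], []).append(t)
    for cid, items in by_class.items():
        if len(items) < 4:
            raise ValueError(
                f"class {cid} has {len(items)} scenes; the 1:1:2 split needs >= 4")

    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cid in sorted(by_class):
        items = by_class[cid]
        order = rng.permutation(len(items))
        k = len(items) // 4
        idx_train, idx_val, idx_test = order[:k], order[k:2 * k], order[2 * k:]
        train.extend(items[i] for i in idx_train)
        val.extend(items[i] for i in idx_val)
        test.extend(items[i] for i in idx_test)
    return DatasetSplit(train=train, validation=val, test=test)


def write_manifest(split: DatasetSplit, path) -> None:
    """Plain-text manifest: one ``<set>\t<class_id>\t<ordinal>`` line per item."""
    path = Path(path)
    with path.open("w") as fh:
        for name, items in (("train", split.train),
                            ("validation", split.validation),
                            ("test", split.test)):
            for i, (_, _, cid) in enumerate(items):
                fh.write(f"{name}\t{cid}\t{i}\n")
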