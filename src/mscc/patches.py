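"""Eightfold geometric augmentation, patch meshing, labeling, balancing.

The augmentation is the dihedral group of order 8: the four right-angle
rotations of the input and of its horizontal mirror.  Images are meshed into
non-overlapping square patches (8x8 by default, which tiles a 256-pixel edge
exactly); a patch is labeled *WithObject* when strictly more than
``criterion_fraction`` of its area is ground-truth foreground, otherwise
*WithoutObject*.  Balancing eightfold-augments the minority label and samples
it down (without replacement) to the majority count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class PatchLabel(enum.Enum):
    WITHOUT_OBJECT = 0
    WITH_OBJECT = 1


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping tiling of a square image by square patches."""

    image_edge: int = 256
    patch_edge: int = 8

    def __post_init__(self):
        if self.image_edge % self.patch_edge != 0:
            raise ValueError(
                f"patch edge {self.patch_edge} does not divide image edge "
                f"{self.image_edge}")

    @property
    def n_rows(self) -> int:
        return self.image_edge // self.patch_edge

    @property
    def n_cols(self) -> int:
        return self.image_edge // self.patch_edge

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def origins(self):
        """Row-major (row, col) top-left corners of every patch."""
        e = self.patch_edge
        return [(r * e, c * e) for r in range(self.n_rows)
                for c in range(self.n_cols)]


@dataclass
class LabeledPatch:
    pixels: np.ndarray           # (edge, edge) intensities
    gt: np.ndarray               # (edge, edge) binary
    label: PatchLabel
    origin: tuple[int, int]      # top-left (row, col) in the parent image
    parent_id: int = 0


def _dihedral(arr: np.ndarray, k: int) -> np.ndarray:
    """Transform index k in 0..7: rotations 0/90/180/270, then the same of
    the horizontally mirrored input."""
    if not 0 <= k < 8:
        raise ValueError("transform index must be in 0..7")
    base = np.fliplr(arr) if k >= 4 else arr
    return np.ascontiguousarray(np.rot90(base, k % 4))


def augment_eightfold(items: list) -> list:
    """Return the 8 dihedral variants of every item (output = 8x input).

    Each item may be a single square 2-D array or a tuple/list of square
    arrays (e.g. an image with its mask) transformed in lockstep.  Output
    order: item 0 transforms 0..7, item 1 transforms 0..7, ...
    """
    out = []
    for item in items:
        grids = item if isinstance(item, (tuple, list)) else (item,)
        for g in grids:
            a = np.asarray(g)
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise ValueError("augment_eightfold expects square 2-D grids")
        for k in range(8):
            if isinstance(item, (tuple, list)):
                out.append(type(item)(_dihedral(np.asarray(g), k) for g in item))
            else:
                out.append(_dihedral(np.asarray(item), k))
    return out


def label_patch(gt_patch: np.ndarray,
                criterion_fraction: float = 0.5) -> PatchLabel:
    """*WithObject* iff foreground area strictly exceeds the criterion.

    With the default 0.5 on an 8x8 patch: 33 of 64 foreground pixels is
    WithObject, exactly 32 is WithoutObject.
    """
    if not 0.0 < criterion_fraction < 1.0:
        raise ValueError("criterion_fraction must be in (0, 1)")
    gt_patch = np.asarray(gt_patch)
    if int(gt_patch.sum()) > criterion_fraction * gt_patch.size:
        return PatchLabel.WITH_OBJECT
    return PatchLabel.WITHOUT_OBJECT


def mesh_patches(image: np.ndarray, gt: np.ndarray, grid: PatchGrid,
                 criterion_fraction: float = 0.5,
                 parent_id: int = 0) -> list[LabeledPatch]:
    """Mesh an image/GT pair into labeled patches, row-major from top-left.

    Reassembling the returned patches reproduces the inputs bit-exactly.
    """
    image = np.asarray(image)
    gt = np.asarray(gt)
    if image.shape != gt.shape:
        raise ValueError("image and GT shapes differ")
    e = grid.patch_edge
    if image.shape[0] % e or image.shape[1] % e:
        raise ValueError(f"patch edge {e} does not divide image shape {image.shape}")
    out = []
    for r0, c0 in grid.origins():
        gp = gt[r0:r0 + e, c0:c0 + e]
        out.append(LabeledPatch(
            pixels=image[r0:r0 + e, c0:c0 + e].copy(), gt=gp.copy(),
            label=label_patch(gp, criterion_fraction),
            origin=(r0, c0), parent_id=parent_id))
    return out


def reassemble(patches: list[LabeledPatch], grid: PatchGrid):
    """Inverse of :func:`mesh_patches` (image, gt) — used as a round-trip check."""
    e = grid.patch_edge
    img = np.zeros((grid.image_edge, grid.image_edge),
                   dtype=patches[0].pixels.dtype)
    gt = np.zeros_like(img)
    for p in patches:
        r0, c0 = p.origin
        img[r0:r0 + e, c0:c0 + e] = p.pixels
        gt[r0:r0 + e, c0:c0 + e] = p.gt
    return img, gt


class BalancingInfeasibleError(ValueError):
    """Eightfold augmentation of the minority cannot reach the majority count."""

    def __init__(self, pool: int, majority: int):
        self.shortfall = majority - pool
        super().__init__(
            f"augmented minority pool has {pool} patches but the majority "
            f"has {majority} (shortfall {self.shortfall})")


def balance_patches(patches: list[LabeledPatch],
                    seed: int = 0) -> list[LabeledPatch]:
    """Equalise the two label counts.

    The minority label's patches are eightfold-augmented and a uniform random
    sample of the augmented pool (without replacement, driven by ``seed``)
    of exactly the majority count replaces the minority.  Already balanced
    input is returned unchanged.
    """
    by_label = {lab: [p for p in patches if p.label is lab]
                for lab in PatchLabel}
    if any(not v for v in by_label.values()):
        raise ValueError("both labels must be present to balance")
    counts = {lab: len(v) for lab, v in by_label.items()}
    minority = min(counts, key=counts.get)
    majority = next(l for l in PatchLabel if l is not minority)
    if counts[minority] == counts[majority]:
        return list(patches)
    pool_size = 8 * counts[minority]
    if pool_size < counts[majority]:
        raise BalancingInfeasibleError(pool_size, counts[majority])

    pool = []
    for p in by_label[minority]:
        for k in range(8):
            pool.append(LabeledPatch(pixels=_dihedral(p.pixels, k),
                                     gt=_dihedral(p.gt, k), label=p.label,
                                     origin=p.origin, parent_id=p.parent_id))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool_size, size=counts[majority], replace=False)
    return by_label[majority] + [pool[i] for i in sorted(chosen)]


def count_labels(patches) -> dict[PatchLabel, int]:
    counts = {lab: 0 for lab in PatchLabel}
    for p in patches:
        counts[p.label] += 1
    return counts


def save_patch_archive(patches: list[LabeledPatch], path) -> None:
    """Serialise a patch set to one array container plus embedded index."""
    np.savez_compressed(
        path,
        pixels=np.stack([p.pixels for p in patches]),
        gt=np.stack([p.gt for p in patches]),
        labels=np.array([p.label.value for p in patches], dtype=np.int8),
        origins=np.array([p.origin for p in patches], dtype=np.int32),
        parent_ids=np.array([p.parent_id for p in patches], dtype=np.int32))


def load_patch_archive(path) -> list[LabeledPatch]:
    with np.load(path) as d:
        return [LabeledPatch(pixels=d["pixels"][i], gt=d["gt"][i],
                             label=PatchLabel(int(d["labels"][i])),
                             origin=tuple(int(v) for v in d["origins"][i]),
                             parent_id=int(d["parent_ids"][i]))
                for i in range(len(d["labels"]))]


def write_patch_index(patches: list[LabeledPatch], path) -> None:
    """Tab-separated index: parent_id, row, col, label."""
    with open(path, "w") as fh:
        fh.write("parent_id\trow\tcol\tlabel\n")
        for p in patches:
            fh.write(f"{p.parent_id}\t{p.origin[0]}\t{p.origin[1]}\t"
                     f"{p.label.name}\n")


def criterion_sensitivity(meshed_gts, fractions=(0.25, 0.5, 0.75)) -> dict:
    """WithObject counts under several labeling criteria.

    ``meshed_gts`` is an iterable of binary GT patches.  Counts are
    non-increasing in the fraction (a stricter criterion never gains
    WithObject patches).
    """
    gts = [np.asarray(g) for g in meshed_gts]
    return {f: sum(label_patch(g, f) is PatchLabel.WITH_OBJECT for g in gts)
            for f in fractions}
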