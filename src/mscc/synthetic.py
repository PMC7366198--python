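"""Synthetic microscopy scenes with exact ground truth.

Generates grayscale image / binary-mask pairs that mimic the layout of a
per-class environmental-microorganism dataset: every class has a fixed shape
family (compact ellipses, thickened random-walk filaments, or spiky
star-blobs) and a wide within-class size range, while foreground and
background intensity distributions overlap so that thresholding alone cannot
solve the segmentation.  All randomness flows through one independent stream
per scene derived from ``(seed, class_id, index)``, so scenes are
reproducible regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SHAPE_KINDS = ("ellipse", "filament", "star-blob")

#: intensity model on [0, 1] before 8-bit quantisation
BG_MEAN, FG_MEAN, NOISE_SD, GRADIENT_AMP = 0.6, 0.4, 0.08, 0.08
#: admissible foreground fraction of a scene
MIN_FG_FRACTION, MAX_FG_FRACTION = 0.02, 0.6


@dataclass
class SyntheticScene:
    """One image/ground-truth pair plus the shape parameters that made it."""

    image: np.ndarray          # uint8 (size, size)
    gt: np.ndarray             # uint8 {0,1}, same shape
    class_id: int
    index: int = 0
    object_descriptors: list = field(default_factory=list)


def shape_kind_for_class(class_id: int) -> str:
    """Classes cycle through the three shape families."""
    return SHAPE_KINDS[class_id % len(SHAPE_KINDS)]


# -- analytic point-in-shape predicates ------------------------------------

def _inside_ellipse(rows, cols, desc) -> np.ndarray:
    cy, cx = desc["center"]
    a, b, theta = desc["a"], desc["b"], desc["theta"]
    dy, dx = rows - cy, cols - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _inside_star(rows, cols, desc) -> np.ndarray:
    cy, cx = desc["center"]
    r0, amp, spikes, phase = desc["r0"], desc["amp"], desc["spikes"], desc["phase"]
    dy, dx = rows - cy, cols - cx
    rr = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx)
    return rr <= r0 * (1.0 + amp * np.cos(spikes * ang + phase))


def _inside_filament(rows, cols, desc) -> np.ndarray:
    """Union of stadiums (radius = half thickness) around a polyline."""
    pts = np.asarray(desc["points"], dtype=float)  # (k, 2) as (row, col)
    radius = desc["thickness"] / 2.0
    inside = np.zeros(rows.shape, dtype=bool)
    p = np.stack([rows, cols], axis=-1)  # (H, W, 2)
    for s, e in zip(pts[:-1], pts[1:]):
        d = e - s
        L2 = float(d @ d)
        if L2 == 0.0:
            dist = np.linalg.norm(p - s, axis=-1)
        else:
            t = np.clip(((p - s) @ d) / L2, 0.0, 1.0)
            proj = s + t[..., None] * d
            dist = np.linalg.norm(p - proj, axis=-1)
        inside |= dist <= radius
    return inside


_PREDICATES = {
    "ellipse": _inside_ellipse,
    "star-blob": _inside_star,
    "filament": _inside_filament,
}


def point_in_shape(row: float, col: float, kind: str, desc: dict) -> bool:
    """Exact membership test for a single point (used by tests as an oracle)."""
    r = np.array([[float(row)]])
    c = np.array([[float(col)]])
    return bool(_PREDICATES[kind](r, c, desc)[0, 0])


def rasterize(descriptors, size: int) -> np.ndarray:
    """GT mask: pixel (r, c) is foreground iff its center lies in any shape."""
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    gt = np.zeros((size, size), dtype=bool)
    for kind, desc in descriptors:
        gt |= _PREDICATES[kind](rows, cols, desc)
    return gt.astype(np.uint8)


# -- shape sampling ---------------------------------------------------------

def _sample_descriptors(kind: str, size: int, rng: np.random.Generator) -> list:
    # per-scene size scale spans >= 2x within a class
    if kind == "ellipse":
        n = int(rng.integers(1, 3))
        descs = []
        for _ in range(n):
            a = size * rng.uniform(0.20, 0.40) / np.sqrt(n)
            b = a * rng.uniform(0.55, 0.95)
            descs.append(("ellipse", {
                "center": (size * rng.uniform(0.3, 0.7), size * rng.uniform(0.3, 0.7)),
                "a": a, "b": b, "theta": rng.uniform(0, np.pi)}))
        return descs
    if kind == "star-blob":
        return [("star-blob", {
            "center": (size * rng.uniform(0.35, 0.65), size * rng.uniform(0.35, 0.65)),
            "r0": size * rng.uniform(0.17, 0.34),
            "amp": rng.uniform(0.2, 0.4),
            "spikes": int(rng.integers(5, 10)),
            "phase": rng.uniform(0, 2 * np.pi)})]
    # filament: bounded random walk
    n_seg = 12
    step = size * rng.uniform(0.08, 0.14)
    pos = np.array([size * rng.uniform(0.3, 0.7), size * rng.uniform(0.3, 0.7)])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(n_seg):
        heading += rng.uniform(-0.9, 0.9)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        pos = np.clip(pos, 0.12 * size, 0.88 * size)
        pts.append(pos.copy())
    return [("filament", {
        "points": np.array(pts),
        "thickness": size * rng.uniform(0.09, 0.18)})]


def _scene_rng(seed: int, class_id: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, class_id, index]))


def generate_scene(class_id: int, size: int, seed: int,
                   index: int = 0) -> SyntheticScene:
    """Generate one deterministic scene.

    Parameters
    ----------
    class_id : non-negative class label; fixes the shape family.
    size : image edge in pixels, at least 32.
    seed : master seed; combined with ``(class_id, index)`` into an
        independent per-scene stream.
    index : scene number within the class.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    if class_id < 0:
        raise ValueError("class_id must be >= 0")
    kind = shape_kind_for_class(class_id)
    rng = _scene_rng(seed, class_id, index)
    for _ in range(32):  # resample until the foreground fraction is in range
        descriptors = _sample_descriptors(kind, size, rng)
        gt = rasterize(descriptors, size)
        frac = gt.mean()
        if MIN_FG_FRACTION <= frac <= MAX_FG_FRACTION:
            break
    else:
        raise RuntimeError("could not sample an admissible scene")

    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    angle = rng.uniform(0, 2 * np.pi)
    plane = (np.cos(angle) * (rows - size / 2) + np.sin(angle) * (cols - size / 2))
    plane *= GRADIENT_AMP / (size / 2)
    intensity = np.where(gt == 1, FG_MEAN, BG_MEAN) + plane
    intensity = intensity + rng.normal(0.0, NOISE_SD, size=(size, size))
    image = np.clip(np.round(np.clip(intensity, 0.0, 1.0) * 255.0), 0, 255)
    return SyntheticScene(image=image.astype(np.uint8), gt=gt,
                          class_id=class_id, index=index,
                          object_descriptors=descriptors)


def generate_dataset(n_classes: int, per_class: int, size: int,
                     seed: int) -> list[SyntheticScene]:
    """Class-balanced list of ``n_classes * per_class`` scenes."""
    if n_classes < 1 or per_class < 1:
        raise ValueError("n_classes and per_class must be >= 1")
    return [generate_scene(c, size, seed, index=i)
            for c in range(n_classes) for i in range(per_class)]


def write_dataset(scenes, root) -> list[tuple[Path, Path]]:
    """Write ``<class>/<idx>.png`` + ``<class>/<idx>_gt.png`` (masks 0/255)."""
    from PIL import Image

    root = Path(root)
    paths = []
    for scene in scenes:
        cdir = root / f"{scene.class_id:02d}"
        cdir.mkdir(parents=True, exist_ok=True)
        ipath = cdir / f"{scene.index:03d}.png"
        gpath = cdir / f"{scene.index:03d}_gt.png"
        Image.fromarray(scene.image, mode="L").save(ipath)
        Image.fromarray((scene.gt * 255).astype(np.uint8), mode="L").save(gpath)
        paths.append((ipath, gpath))
    return paths
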