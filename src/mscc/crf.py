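"""Fully connected binary CRF with Gaussian edge potentials.

The energy of a labeling ``x`` is ``E(x) = sum_i U(x_i) + sum_{i<j}
[x_i != x_j] * k(f_i, f_j)`` — Potts compatibility, so only disagreeing
pixel pairs pay the pairwise price.  The pairwise kernel combines an
appearance term (close positions *and* similar grayscale intensities) and a
smoothness term (close positions only):

``k(f_i, f_j) = w1 * exp(-|pi-pj|^2 / 2 sa^2 - (Ii-Ij)^2 / 2 sb^2)
              + w2 * exp(-|pi-pj|^2 / 2 sg^2)``

Unary costs come from the binarised network output: a foreground pixel gets
label likelihood ``1 - eps`` and cost ``-log`` of it.  Inference is parallel
mean-field; on small grids message passing uses the exact dense kernel
matrix, on larger images a truncated window (the Gaussians decay to nothing
beyond a few scales) evaluated by shifting the marginal planes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class CRFParams:
    """Kernel weights/scales and inference settings.

    ``sigma_alpha``/``sigma_gamma`` are in pixels, ``sigma_beta`` in 8-bit
    intensity units.  ``truncation`` is the window radius in units of the
    spatial sigma beyond which a kernel is treated as zero;
    ``exact_threshold`` is the pixel count up to which the dense kernel
    matrix is used instead.
    """

    w1: float = 5.0
    w2: float = 3.0
    sigma_alpha: float = 40.0
    sigma_beta: float = 10.0
    sigma_gamma: float = 3.0
    iterations: int = 5
    unary_clamp_eps: float = 0.1
    truncation: float = 4.0
    exact_threshold: int = 1024

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("kernel weights must be >= 0")
        if min(self.sigma_alpha, self.sigma_beta, self.sigma_gamma) <= 0:
            raise ValueError("all kernel scales must be > 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0.0 < self.unary_clamp_eps < 0.5:
            raise ValueError("unary_clamp_eps must be in (0, 0.5)")


@dataclass(frozen=True)
class PixelFeature:
    position: tuple[float, float]  # (row, col), 0-based pixel units
    intensity: float               # grayscale in [0, 255]


ENERGY_SIZE_LIMIT = 4096  # pixels; exact O(N^2) summation beyond this refused


class GridTooLargeError(ValueError):
    """Raised when exact energy evaluation is requested on a large grid."""


def unary_from_mask(mask: np.ndarray, eps: float) -> np.ndarray:
    """Per-pixel label costs ``-log L`` from a binary mask.

    Returns an array of shape ``(2, H, W)``: plane 0 is the cost of labeling
    the pixel background, plane 1 foreground.  A foreground mask pixel has
    ``L(fg) = 1 - eps`` and ``L(bg) = eps`` (and symmetrically for
    background), so costs are finite for any ``eps`` in (0, 0.5).
    """
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    cost_hit, cost_miss = -np.log(1.0 - eps), -np.log(eps)
    unary = np.empty((2,) + mask.shape, dtype=np.float64)
    unary[1] = np.where(mask == 1, cost_hit, cost_miss)
    unary[0] = np.where(mask == 1, cost_miss, cost_hit)
    return unary


def pairwise_kernel(fi: PixelFeature, fj: PixelFeature,
                    params: CRFParams) -> float:
    """Evaluate the two-kernel potential for one feature pair (symmetric)."""
    dp2 = ((fi.position[0] - fj.position[0]) ** 2
           + (fi.position[1] - fj.position[1]) ** 2)
    di2 = (fi.intensity - fj.intensity) ** 2
    appearance = np.exp(-dp2 / (2 * params.sigma_alpha ** 2)
                        - di2 / (2 * params.sigma_beta ** 2))
    smoothness = np.exp(-dp2 / (2 * params.sigma_gamma ** 2))
    return float(params.w1 * appearance + params.w2 * smoothness)


def _dense_kernel_matrix(image: np.ndarray, params: CRFParams) -> np.ndarray:
    """Full (N, N) pairwise kernel with a zero diagonal."""
    h, w = image.shape
    rows, cols = np.mgrid[0:h, 0:w]
    pos = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(np.float64)
    inten = image.astype(np.float64).ravel()
    dp2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    di2 = (inten[:, None] - inten[None, :]) ** 2
    k = (params.w1 * np.exp(-dp2 / (2 * params.sigma_alpha ** 2)
                            - di2 / (2 * params.sigma_beta ** 2))
         + params.w2 * np.exp(-dp2 / (2 * params.sigma_gamma ** 2)))
    np.fill_diagonal(k, 0.0)
    return k


def total_energy(labels: np.ndarray, unary: np.ndarray, image: np.ndarray,
                 params: CRFParams) -> float:
    """Exact energy of a labeling; small grids only (each pair counted once)."""
    labels = np.asarray(labels)
    if labels.size > ENERGY_SIZE_LIMIT:
        raise GridTooLargeError(
            f"exact energy needs <= {ENERGY_SIZE_LIMIT} pixels "
            f"(got {labels.size}); use mean_field_refine for inference")
    if labels.shape != image.shape or unary.shape != (2,) + labels.shape:
        raise ValueError("labels, unary and image shapes are inconsistent")
    lab = labels.ravel()
    e_unary = float(unary.reshape(2, -1)[lab, np.arange(lab.size)].sum())
    k = _dense_kernel_matrix(image, params)
    disagree = lab[:, None] != lab[None, :]
    return e_unary + 0.5 * float(k[disagree].sum())


def _windowed_message(q: np.ndarray, image: np.ndarray,
                      params: CRFParams) -> np.ndarray:
    """``S(l) = sum_{j != i} k_ij Q_j(l)`` via truncated-window shifts."""
    h, w = image.shape
    inten = image.astype(np.float64)
    s = np.zeros_like(q)

    def accumulate(radius, spatial_sigma, with_intensity, weight):
        r = int(min(radius, max(h, w) - 1))
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dy == 0 and dx == 0:
                    continue
                g = weight * np.exp(-(dy * dy + dx * dx)
                                    / (2 * spatial_sigma ** 2))
                if g < 1e-12:
                    continue
                ys = slice(max(0, dy), min(h, h + dy))
                xs = slice(max(0, dx), min(w, w + dx))
                yt = slice(max(0, -dy), min(h, h - dy))
                xt = slice(max(0, -dx), min(w, w - dx))
                for l in range(2):
                    contrib = g * q[l][ys, xs]
                    if with_intensity:
                        di = inten[yt, xt] - inten[ys, xs]
                        contrib = contrib * np.exp(
                            -di * di / (2 * params.sigma_beta ** 2))
                    s[l][yt, xt] += contrib

    if params.w1 > 0:
        accumulate(np.ceil(params.truncation * params.sigma_alpha),
                   params.sigma_alpha, True, params.w1)
    if params.w2 > 0:
        accumulate(np.ceil(params.truncation * params.sigma_gamma),
                   params.sigma_gamma, False, params.w2)
    return s


def mean_field_refine(unary: np.ndarray, image: np.ndarray,
                      params: CRFParams):
    """Parallel mean-field inference.

    Marginals start from the unary soft-max; each of ``params.iterations``
    sweeps sets ``Q_i(l) proportional to exp(-U_i(l) - sum_{l' != l}
    sum_{j != i} k_ij Q_j(l'))`` simultaneously at every pixel.  Returns the
    per-pixel arg-max labels and the final marginals ``(2, H, W)``; with zero
    iterations the labels are simply the unary arg-min.
    """
    unary = np.asarray(unary, dtype=np.float64)
    if not np.isfinite(unary).all():
        raise ValueError("unary costs must be finite")
    image = np.asarray(image)
    if unary.shape != (2,) + image.shape:
        raise ValueError("unary must have shape (2, H, W) matching the image")

    def normalise(logq):
        logq = logq - logq.max(axis=0, keepdims=True)
        q = np.exp(logq)
        return q / q.sum(axis=0, keepdims=True)

    q = normalise(-unary)
    exact = image.size <= params.exact_threshold
    if exact:
        kmat = _dense_kernel_matrix(image, params)
    self_weight = params.w1 + params.w2
    for _ in range(params.iterations):
        if exact:
            s = (kmat @ q.reshape(2, -1).T).T.reshape(q.shape)
        else:
            s = _windowed_message(q, image, params)
        # message for label l is the mass of the *other* label around i;
        # the dense matrix already excludes j == i, the windowed path too
        message = s[::-1].copy() if not exact else s[::-1]
        q = normalise(-unary - message)
    labels = q.argmax(axis=0).astype(np.uint8)
    return labels, q


def refine_mask(mask: np.ndarray, image: np.ndarray,
                params: CRFParams) -> np.ndarray:
    """Convenience: binarised-network mask -> unary -> mean field -> mask."""
    unary = unary_from_mask(mask, params.unary_clamp_eps)
    labels, _ = mean_field_refine(unary, image, params)
    return labels


def energy_trace(mask: np.ndarray, image: np.ndarray,
                 params: CRFParams) -> list[float]:
    """Per-iteration energy of the arg-max labeling on a small grid."""
    unary = unary_from_mask(mask, params.unary_clamp_eps)
    trace = []
    for it in range(params.iterations + 1):
        labels, _ = mean_field_refine(unary, image,
                                      replace(params, iterations=it))
        trace.append(total_energy(labels, unary, image, params))
    return trace


def write_energy_trace_csv(mask: np.ndarray, image: np.ndarray,
                           params: CRFParams, path) -> None:
    """Diagnostics dump: iteration, energy (small inputs only)."""
    with open(path, "w") as fh:
        fh.write("iteration,energy\n")
        for it, e in enumerate(energy_trace(mask, image, params)):
            fh.write(f"{it},{e:.8f}\n")
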