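"""Textural feature extraction and the pack-allocation fitness.

The segmentation search is driven by a scalar score built from classical
per-patch texture descriptors: local variance, local entropy (8-bin) and
mean gradient magnitude on non-overlapping patches, plus the fine/coarse
band energies of a 3-level Gaussian/Laplacian image pyramid.  The
pack-allocation score combines the mean descriptor level, a clustering
misfit penalty normalized by a descriptor-count "time" proxy and the
resolution-band energy, and the number of search packs:

    F(d, P) = [mean(extf) - (fc / fct) / (rho_high + rho_low)] + P - 1

The image is standardized (zero mean, unit variance) before any descriptor
or pyramid computation, so the score is invariant to affine rescaling of
raw intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TextureFeatureSet",
    "AllocationScore",
    "extract_texture_features",
    "pack_allocation_score",
    "segmentation_fitness",
    "dump_features_csv",
]


@dataclass
class TextureFeatureSet:
    """Per-patch texture descriptors and global band energies.

    extf     : (n_patches, 3) array; columns variance, entropy, grad_mean
    rho_high : energy of the finest Laplacian band (high-resolution features)
    rho_low  : energy of the coarsest pyramid level (low-resolution features)
    fc       : within-patch 2-means misfit of the z-scored descriptors
    fct      : number of descriptors processed (count proxy for time)
    omega    : (n_patches,) binary variation flags
    patch_grid : (rows, cols) of the patch tiling
    """

    extf: np.ndarray
    rho_high: float
    rho_low: float
    fc: float
    fct: float
    omega: np.ndarray
    patch_grid: tuple[int, int]


@dataclass
class AllocationScore:
    F_dP: float
    diff_time: float
    seq_diff: float
    pack_count: int


def _standardize(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    std = img.std()
    if std == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / std


def _patch_descriptors(img: np.ndarray, patch_size: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    rows, cols = h // patch_size, w // patch_size
    gy, gx = np.gradient(img)
    grad_mag = np.hypot(gy, gx)
    desc = np.empty((rows * cols, 3))
    k = 0
    for r in range(rows):
        for c in range(cols):
            patch = img[r * patch_size:(r + 1) * patch_size,
                        c * patch_size:(c + 1) * patch_size]
            var = patch.var()
            lo, hi = patch.min(), patch.max()
            if hi > lo:
                hist, _ = np.histogram(patch, bins=8, range=(lo, hi))
                p = hist / hist.sum()
                p = p[p > 0]
                ent = float(-(p * np.log2(p)).sum())
            else:
                ent = 0.0
            gm = grad_mag[r * patch_size:(r + 1) * patch_size,
                          c * patch_size:(c + 1) * patch_size].mean()
            desc[k] = (var, ent, gm)
            k += 1
    return desc, (rows, cols)


def _zscore_rows(desc: np.ndarray) -> np.ndarray:
    mu = desc.mean(axis=0)
    sd = desc.std(axis=0)
    sd[sd == 0] = 1.0
    return (desc - mu) / sd


def _two_means_misfit(z: np.ndarray, iters: int = 20) -> float:
    """Deterministic 2-means inertia on z-scored descriptor rows.

    Initialized from the two mutually farthest rows (ties broken by index),
    Lloyd iterations for a fixed count; returns the mean squared distance of
    each row to its centroid.
    """
    n = z.shape[0]
    if n < 2:
        return 0.0
    # farthest pair via the row of max norm and the row farthest from it
    i0 = int(np.argmax((z ** 2).sum(axis=1)))
    d0 = ((z - z[i0]) ** 2).sum(axis=1)
    i1 = int(np.argmax(d0))
    centers = np.stack([z[i0], z[i1]])
    for _ in range(iters):
        d = ((z[:, None, :] - centers[None]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1)
        for c in range(2):
            if np.any(labels == c):
                centers[c] = z[labels == c].mean(axis=0)
    d = ((z[:, None, :] - centers[None]) ** 2).sum(axis=2)
    return float(d.min(axis=1).mean())


def _pyramid_energies(img: np.ndarray, levels: int = 3) -> tuple[float, float]:
    """Mean-square energy of the finest Laplacian band and coarsest level."""
    current = img
    high = None
    for _ in range(levels):
        smoothed = ndimage.gaussian_filter(current, sigma=1.0, mode="nearest")
        if high is None:
            high = current - smoothed  # finest detail band
        current = smoothed[::2, ::2]
    rho_high = float((high ** 2).mean())
    rho_low = float((current ** 2).mean())
    return rho_high, rho_low


def extract_texture_features(image: np.ndarray, patch_size: int = 8,
                             tau: float = 2.0) -> TextureFeatureSet:
    """Compute the per-patch descriptor set and band energies.

    Parameters
    ----------
    image : 2-D grayscale array (any intensity scale; standardized inside).
    patch_size : side of the non-overlapping square patches; the image must
        tile into at least 4 patches.
    tau : variation threshold in median-absolute-deviation units; a patch's
        omega flag is 1 iff its z-scored descriptor vector is farther than
        tau MADs from the patch-population median.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    rows, cols = img.shape[0] // patch_size, img.shape[1] // patch_size
    if rows * cols < 4:
        raise ValueError(
            f"patch_size {patch_size} yields only {rows * cols} patches; need >= 4")
    if img.std() == 0:
        warnings.warn("constant image: degenerate texture (all-zero descriptors)",
                      RuntimeWarning)
        n = rows * cols
        return TextureFeatureSet(
            extf=np.zeros((n, 3)), rho_high=0.0, rho_low=0.0, fc=0.0,
            fct=float(3 * n), omega=np.zeros(n, dtype=int),
            patch_grid=(rows, cols))
    std_img = _standardize(img)
    desc, grid = _patch_descriptors(std_img, patch_size)
    z = _zscore_rows(desc)
    med = np.median(z, axis=0)
    dist = np.abs(z - med).sum(axis=1)
    mad = np.median(np.abs(dist - np.median(dist)))
    if mad == 0:
        omega = (dist > 0).astype(int) * (dist > tau * (dist.mean() + 1e-12)).astype(int)
    else:
        omega = (dist - np.median(dist) > tau * mad).astype(int)
    rho_high, rho_low = _pyramid_energies(std_img)
    fc = _two_means_misfit(z)
    fct = float(desc.size)
    return TextureFeatureSet(extf=desc, rho_high=rho_high, rho_low=rho_low,
                             fc=fc, fct=fct, omega=omega, patch_grid=grid)


def pack_allocation_score(features: TextureFeatureSet, pack_count: int,
                          image: np.ndarray | None = None) -> AllocationScore:
    """Evaluate the pack-allocation score for a feature set.

    F(d,P) = [mean(extf) - (fc/fct)/(rho_high+rho_low)] + pack_count - 1.
    seq_diff sums (pack_count - (rho_high + rho_low)) over the patch index.
    diff_time (the original-vs-preprocessed comparison) is the mean absolute
    descriptor difference between the image and a Gaussian-blurred (sigma=1)
    copy; it is 0 when no image is supplied.
    """
    if pack_count < 1:
        raise ValueError("pack_count must be >= 1")
    if features.fct <= 0:
        raise ValueError("fct must be positive")
    rho_total = features.rho_high + features.rho_low
    if rho_total <= 0:
        raise ValueError("rho_high + rho_low must be positive "
                         "(constant image has no texture)")
    F_dP = (float(features.extf.mean())
            - (features.fc / features.fct) / rho_total
            + pack_count - 1)
    n_patches = features.extf.shape[0]
    seq_diff = float(n_patches * (pack_count - rho_total))
    diff_time = 0.0
    if image is not None:
        img = _standardize(np.asarray(image, dtype=float))
        blurred = ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")
        patch = int(np.asarray(image).shape[0] // features.patch_grid[0])
        d_org, _ = _patch_descriptors(img, patch)
        d_ppc, _ = _patch_descriptors(blurred, patch)
        diff_time = float(np.abs(d_org - d_ppc).mean())
    return AllocationScore(F_dP=F_dP, diff_time=diff_time,
                           seq_diff=seq_diff, pack_count=pack_count)


def _masked_descriptor_means(desc: np.ndarray, weights: np.ndarray
                             ) -> np.ndarray | None:
    total = weights.sum()
    if total <= 0:
        return None
    return (desc * weights[:, None]).sum(axis=0) / total


def segmentation_fitness(image: np.ndarray, predicted_mask: np.ndarray,
                         reference_mask: np.ndarray | None = None,
                         patch_size: int = 8) -> float:
    """Scalar fitness of a candidate segmentation (lower is better).

    Supervised (reference given): 1 - Dice(predicted, reference), in [0, 1].
    Unsupervised: negative texture contrast between inside-mask and
    outside-mask patch descriptors (z-scored); a mask that isolates a
    texturally distinct region scores lower (better).
    """
    image = np.asarray(image, dtype=float)
    predicted = np.asarray(predicted_mask).astype(bool)
    if predicted.shape != image.shape:
        raise ValueError("mask shape must equal image shape")
    if reference_mask is not None:
        reference = np.asarray(reference_mask).astype(bool)
        if reference.shape != image.shape:
            raise ValueError("mask shape must equal image shape")
        inter = np.logical_and(predicted, reference).sum()
        denom = predicted.sum() + reference.sum()
        if denom == 0:
            return 0.0  # both empty: identical
        return 1.0 - 2.0 * inter / denom
    # unsupervised: descriptor contrast across the mask boundary
    std_img = _standardize(image)
    desc, grid = _patch_descriptors(std_img, patch_size)
    z = _zscore_rows(desc)
    rows, cols = grid
    cover = np.empty(rows * cols)
    k = 0
    for r in range(rows):
        for c in range(cols):
            cover[k] = predicted[r * patch_size:(r + 1) * patch_size,
                                 c * patch_size:(c + 1) * patch_size].mean()
            k += 1
    inside = _masked_descriptor_means(z, cover)
    outside = _masked_descriptor_means(z, 1.0 - cover)
    if inside is None or outside is None:
        return 0.0  # all-in or all-out mask: no contrast measurable
    return -float(np.linalg.norm(inside - outside))


def dump_features_csv(features: TextureFeatureSet, path) -> None:
    """One row per patch: row, col, variance, entropy, grad_mean, omega."""
    import csv

    rows, cols = features.patch_grid
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "variance", "entropy", "grad_mean", "omega"])
        k = 0
        for r in range(rows):
            for c in range(cols):
                v, e, g = features.extf[k]
                writer.writerow([r, c, v, e, g, int(features.omega[k])])
                k += 1
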