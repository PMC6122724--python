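"""Breast, parenchyma and peritumoral-shell segmentation.

The breast is the largest connected above-Otsu component of the
pre-contrast volume with holes filled.  Fibroglandular parenchyma is
segmented by fuzzy c-means clustering of the pre-contrast intensities
inside the breast (tumor excluded): on non-fat-saturated T1 images fat is
bright and parenchyma dark, so parenchyma is the darker-centroid cluster
(set ``fat_sat=True`` to take the brighter one).  The tumor-surrounding
shell is every region voxel within a Euclidean distance (in mm, honoring
anisotropic spacing) of the tumor surface.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


class FCMResult(NamedTuple):
    centers: np.ndarray        # sorted ascending
    memberships: np.ndarray    # (n_samples, n_clusters), rows sum to 1
    objective: list            # per-iteration objective values
    converged: bool


def make_breast_mask(volume) -> np.ndarray:
    """Largest connected above-Otsu component, holes filled."""
    volume = np.asarray(volume, dtype=float)
    if np.ptp(volume) == 0:
        raise ValueError("cannot threshold a constant volume")
    thr = threshold_otsu(volume)
    fg = volume > thr
    lab, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no foreground voxels above the Otsu threshold")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def fuzzy_cmeans_1d(x, n_clusters=2, m=2.0, tol=1e-5, max_iter=200, seed=0) -> FCMResult:
    """Fuzzy c-means on a 1-D sample.

    Standard alternating updates with fuzziness exponent ``m``; centers are
    initialized k-means++-style from a seeded stream; iteration stops when
    the largest center movement falls below ``tol``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if x.size < n_clusters:
        raise ValueError("need at least as many samples as clusters")
    rng = np.random.default_rng(seed)

    centers = np.empty(n_clusters)
    centers[0] = x[rng.integers(x.size)]
    for k in range(1, n_clusters):
        d2 = np.min((x[:, None] - centers[None, :k]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers[k:] = x[rng.integers(x.size, size=n_clusters - k)]
            break
        centers[k] = x[rng.choice(x.size, p=d2 / total)]

    power = 2.0 / (m - 1.0)
    objective = []
    converged = False
    u = None
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        zero = d < 1e-12
        d = np.where(zero, 1e-12, d)
        inv = d ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
        u[zero.any(axis=1)] = zero[zero.any(axis=1)].astype(float)
        um = u ** m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        objective.append(float((um * d ** 2).sum()))
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fuzzy c-means did not converge in {max_iter} iterations "
            f"(last center shift {shift:.2e})", RuntimeWarning)
    order = np.argsort(centers)
    return FCMResult(centers[order], u[:, order], objective, converged)


def fcm_parenchyma(volume, breast_mask, tumor_mask=None, n_clusters=2,
                   fat_sat=False, m=2.0, tol=1e-5, max_iter=200, seed=0):
    """Parenchyma mask from fuzzy c-means on breast intensities.

    Clustering runs on voxels inside the breast mask minus the tumor; the
    parenchyma cluster is the darkest centroid (brightest if ``fat_sat``).
    """
    volume = np.asarray(volume, dtype=float)
    breast_mask = np.asarray(breast_mask, dtype=bool)
    region = breast_mask.copy()
    if tumor_mask is not None:
        region &= ~np.asarray(tumor_mask, dtype=bool)
    if region.sum() < n_clusters:
        raise ValueError("breast mask (minus tumor) has fewer voxels than clusters")
    res = fuzzy_cmeans_1d(volume[region], n_clusters=n_clusters, m=m,
                          tol=tol, max_iter=max_iter, seed=seed)
    target = n_clusters - 1 if fat_sat else 0  # centers sorted ascending
    assign = res.memberships.argmax(axis=1)
    mask = np.zeros_like(region)
    mask[region] = assign == target
    return mask


def tumor_shell(tumor_mask, region_mask, spacing=(1.0, 1.0, 1.0),
                distance_mm=20.0) -> np.ndarray:
    """Region voxels within ``distance_mm`` of the tumor, tumor excluded.

    Distances are exact Euclidean distances in mm to the nearest tumor
    voxel, computed with the anisotropic-sampling distance transform.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    dist = ndimage.distance_transform_edt(~tumor_mask, sampling=spacing)
    return region_mask & ~tumor_mask & (dist <= distance_mm)
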