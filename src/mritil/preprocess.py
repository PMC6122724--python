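"""Harmonization of raw DCE series.

Four steps, applied in this order: multiplicative bias-field correction,
phase standardization (pre / ~2.5 min early / ~7.5 min late), intensity
normalization by the interquartile mean of pre-contrast parenchyma, and
resampling to 1-mm isotropic voxels.

Bias correction is a light-weight surrogate for N4: a second-order 3-D
polynomial is fitted to the log-intensities inside the breast mask with
iteratively reweighted least squares (Tukey biweight), so that tissue
structure is treated as outliers and only the smooth shading component is
captured.  The exponentiated fit, normalized to mean 1 over the mask, is
divided out.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .core import DCESeries


class BiasResult(NamedTuple):
    volume: np.ndarray
    field: np.ndarray
    coefficients: np.ndarray


class PhaseTriplet(NamedTuple):
    pre: np.ndarray
    early: np.ndarray
    late: np.ndarray
    times: tuple


class NormalizationResult(NamedTuple):
    volumes: tuple
    reference: float


def _poly_design(shape, mask):
    coords = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij")
    flat = [c[mask] if mask is not None else c.ravel() for c in coords]
    terms = [np.ones_like(flat[0])]
    for i in range(3):
        terms.append(flat[i])
    for i in range(3):
        for j in range(i, 3):
            terms.append(flat[i] * flat[j])
    return np.column_stack(terms)


def correct_bias(volume, mask, n_iter=10) -> BiasResult:
    """Estimate and remove a smooth multiplicative bias field.

    Returns the corrected volume, the estimated field (mean 1 over the
    mask) and the polynomial coefficients of its log.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask and volume must share one grid")
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("breast mask is empty")
    n_coef = 10  # constant + 3 linear + 6 quadratic terms
    if n_vox < n_coef:
        raise ValueError(
            f"breast mask has {n_vox} voxels; >= {n_coef} needed for the "
            "second-order polynomial fit")
    vals = volume[mask]
    if np.any(vals <= 0):
        raise ValueError("volume must be positive inside the mask")

    X = _poly_design(volume.shape, mask)
    y = np.log(vals)

    def tukey_weights(residuals):
        scale = 1.4826 * np.median(np.abs(residuals - np.median(residuals)))
        if scale <= 1e-12:
            return None  # residuals already flat
        u = residuals / (4.685 * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        return w if w.sum() >= n_coef else np.ones_like(residuals)

    # Initialize from a constant (median) model: the dominant tissue drives
    # the fit and darker/brighter minority tissue starts down-weighted, so
    # the polynomial tracks shading rather than anatomy.
    w = tukey_weights(y - np.median(y))
    if w is None:
        w = np.ones_like(y)
    coef = np.zeros(X.shape[1])
    for _ in range(max(1, n_iter)):
        Xw = X * w[:, None]
        coef, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
        w_new = tukey_weights(y - X @ coef)
        if w_new is None:
            break
        w = w_new

    X_full = _poly_design(volume.shape, None)
    log_field = (X_full @ coef).reshape(volume.shape)
    field = np.exp(log_field)
    field /= field[mask].mean()
    return BiasResult(volume / field, field, coef)


def select_phases(series: DCESeries, early_target=2.5, late_target=7.5,
                  early_window=(1.0, 4.0), late_min=5.0) -> PhaseTriplet:
    """Pick the pre / early / late volumes from a multi-phase series.

    Early phase: post-contrast scan with acquisition time in
    ``early_window`` minutes nearest ``early_target``; late phase: scan
    later than ``late_min`` minutes nearest ``late_target``.  Ties break
    toward the earlier scan.
    """
    times = series.times_min
    post = [(t, v) for t, v in zip(times[1:], series.volumes[1:])]

    def nearest(cands, target):
        return min(cands, key=lambda tv: (abs(tv[0] - target), tv[0]))

    early_cands = [(t, v) for t, v in post if early_window[0] <= t <= early_window[1]]
    if not early_cands:
        raise ValueError(
            f"no early post-contrast phase in [{early_window[0]}, "
            f"{early_window[1]}] min")
    late_cands = [(t, v) for t, v in post if t > late_min]
    if not late_cands:
        raise ValueError(f"no late post-contrast phase later than {late_min} min")
    t_e, early = nearest(early_cands, early_target)
    t_l, late = nearest(late_cands, late_target)
    return PhaseTriplet(series.volumes[0], early, late, (times[0], t_e, t_l))


def normalize_intensity(volumes, parenchyma_mask) -> NormalizationResult:
    """Divide all phases by the interquartile mean of pre-contrast parenchyma.

    The reference is the mean of pre-contrast parenchyma voxels whose
    intensities fall inside the closed [25th, 75th] percentile band.
    """
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)
    if parenchyma_mask.sum() < 8:
        raise ValueError("parenchyma mask needs >= 8 voxels for normalization")
    pre = np.asarray(volumes[0], dtype=float)
    vals = pre[parenchyma_mask]
    lo, hi = np.percentile(vals, [25.0, 75.0])
    band = vals[(vals >= lo) & (vals <= hi)]
    reference = float(band.mean())
    if reference <= 0:
        raise ValueError("interquartile parenchyma reference is non-positive")
    out = tuple(np.asarray(v, dtype=float) / reference for v in volumes)
    return NormalizationResult(out, reference)


def resample_isotropic(volume, spacing, target=1.0, is_mask=False):
    """Resample to isotropic voxels (default 1 mm).

    Trilinear interpolation for intensities, nearest-neighbor for masks
    (re-binarized at 0.5).  Returns ``(resampled, new_spacing)``.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be positive")
    volume = np.asarray(volume)
    new_spacing = (target,) * volume.ndim
    if all(abs(s - target) < 1e-12 for s in spacing):
        out = volume.astype(bool) if is_mask else volume.astype(float)
        return out.copy(), new_spacing
    zoom = [s / target for s in spacing]
    if is_mask:
        res = ndimage.zoom(volume.astype(float), zoom, order=0,
                           mode="nearest", grid_mode=True)
        return res > 0.5, new_spacing
    res = ndimage.zoom(volume.astype(float), zoom, order=1,
                       mode="nearest", grid_mode=True)
    return res, new_spacing
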