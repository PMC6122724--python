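"""The 17 imaging features.

Five groups, computed on the harmonized 1-mm grid:

* M1-M5 — tumor morphology: volume (mm^3), sphericity, surface-to-volume
  ratio (1/mm), mean and SD of margin sharpness (gradient of the early
  post-contrast volume along the outward surface normal at the boundary).
* TEX1-TEX4 — Haralick statistics (correlation, cluster shade, energy,
  entropy) of the SER map inside the tumor, from a single symmetric
  gray-level co-occurrence matrix pooled over the 13 unique 3-D
  unit-distance offsets; SER clipped to [0, 3] and quantized to 32 levels.
* FTV1-FTV2 — functional tumor volume: absolute volume with SER > 1.0 /
  SER > 1.5 (fast uptake-washout subvolume).
* BPE1-BPE4 — background parenchymal enhancement: absolute volume of
  parenchyma with PE > 0.2 / PE > 0.6 and the same counts as fractions of
  all parenchyma voxels.
* TSBPE1-TSBPE2 — mean PE and mean SER in the parenchyma shell within 2 cm
  of the tumor surface.

All threshold comparisons are strict, following the feature definitions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .core import FEATURE_NAMES, KineticMaps, SegmentationSet, voxel_volume_mm3
from .kinetics import compute_kinetic_maps

GLCM_LEVELS = 32
SER_CLIP = (0.0, 3.0)

def _unique_offsets():
    # 13 unique unit-distance 3-D offsets: one representative per +/- pair
    # (lexicographically positive).
    offsets = []
    for a in (0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                if (a, b, c) <= (0, 0, 0):
                    continue
                offsets.append((a, b, c))
    return offsets


GLCM_OFFSETS = _unique_offsets()
assert len(GLCM_OFFSETS) == 13


def morphology_features(tumor_mask, early, spacing=(1.0, 1.0, 1.0)):
    """M1 volume, M2 sphericity, M3 surface/volume, M4/M5 margin sharpness."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty (morphology stage)")
    early = np.asarray(early, dtype=float)
    voxvol = voxel_volume_mm3(spacing)
    m1 = float(tumor_mask.sum()) * voxvol

    # light smoothing before meshing: raw binary marching cubes keeps the
    # voxel staircase and overestimates curved surface areas by ~8%
    padded = ndimage.gaussian_filter(np.pad(tumor_mask.astype(float), 2), sigma=1.0)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(mesh_surface_area(verts, faces))
    m2 = np.pi ** (1.0 / 3.0) * (6.0 * m1) ** (2.0 / 3.0) / area
    m3 = area / m1

    boundary = tumor_mask & ~ndimage.binary_erosion(tumor_mask)
    # outward normal from the smoothed signed distance (positive outside)
    sd = (ndimage.distance_transform_edt(~tumor_mask, sampling=spacing)
          - ndimage.distance_transform_edt(tumor_mask, sampling=spacing))
    sd = ndimage.gaussian_filter(sd, sigma=1.0)
    normals = np.stack(np.gradient(sd, *spacing))
    norm = np.sqrt((normals ** 2).sum(axis=0))
    norm = np.where(norm > 1e-12, norm, 1.0)
    normals /= norm
    grad = np.stack(np.gradient(early, *spacing))
    directional = np.abs((grad * normals).sum(axis=0))[boundary]
    m4 = float(directional.mean())
    m5 = float(directional.std(ddof=1)) if directional.size > 1 else 0.0
    return {"M1": m1, "M2": float(m2), "M3": float(m3), "M4": m4, "M5": m5}


def _quantize_ser(ser, levels=GLCM_LEVELS, clip=SER_CLIP):
    clipped = np.clip(ser, *clip)
    q = np.floor((clipped - clip[0]) / (clip[1] - clip[0]) * levels).astype(int)
    return np.minimum(q, levels - 1)


def glcm_matrix(ser, mask, levels=GLCM_LEVELS, clip=SER_CLIP):
    """Symmetric pooled-offset GLCM of the quantized SER map, sum 1."""
    mask = np.asarray(mask, dtype=bool)
    q = _quantize_ser(np.where(mask, ser, 0.0), levels, clip)
    counts = np.zeros((levels, levels))
    for off in GLCM_OFFSETS:
        src = tuple(slice(max(0, -o), (None if o <= 0 else -o) or None) for o in off)
        dst = tuple(slice(max(0, o), (None if o >= 0 else o) or None) for o in off)
        both = mask[src] & mask[dst]
        if not both.any():
            continue
        i = q[src][both]
        j = q[dst][both]
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no tumor-internal voxel pairs for the GLCM")
    return counts / total


def glcm_features(ser, tumor_mask, valid=None):
    """TEX1 correlation, TEX2 cluster shade, TEX3 energy, TEX4 entropy."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if valid is not None:
        tumor_mask = tumor_mask & np.asarray(valid, dtype=bool)
    if tumor_mask.sum() < 2:
        raise ValueError("need >= 2 valid tumor voxels for texture (GLCM stage)")
    p = glcm_matrix(ser, tumor_mask)
    idx = np.arange(p.shape[0])
    px = p.sum(axis=1)
    mu = float((idx * px).sum())
    var = float(((idx - mu) ** 2 * px).sum())
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    if var > 1e-15:
        corr = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        corr = 0.0  # constant map: correlation undefined, reported as 0
    shade = float((((ii + jj - 2.0 * mu) ** 3) * p).sum())
    energy = float((p ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"TEX1": corr, "TEX2": shade, "TEX3": energy, "TEX4": entropy}


def ftv_features(ser, tumor_mask, valid, spacing=(1.0, 1.0, 1.0)):
    """FTV1/FTV2: absolute tumor volume with SER > 1.0 / > 1.5 (strict)."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    sel = tumor_mask & np.asarray(valid, dtype=bool)
    voxvol = voxel_volume_mm3(spacing)
    s = np.asarray(ser, dtype=float)[sel]
    return {
        "FTV1": float((s > 1.0).sum()) * voxvol,
        "FTV2": float((s > 1.5).sum()) * voxvol,
    }


def bpe_features(pe, parenchyma_mask, valid, spacing=(1.0, 1.0, 1.0)):
    """BPE1/2: parenchyma volume with PE > 0.2 / > 0.6; BPE3/4: fractions."""
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)
    n_par = int(parenchyma_mask.sum())
    if n_par == 0:
        raise ValueError("parenchyma mask is empty (BPE stage)")
    sel = parenchyma_mask & np.asarray(valid, dtype=bool)
    voxvol = voxel_volume_mm3(spacing)
    p = np.asarray(pe, dtype=float)[sel]
    n02 = float((p > 0.2).sum())
    n06 = float((p > 0.6).sum())
    return {
        "BPE1": n02 * voxvol,
        "BPE2": n06 * voxvol,
        "BPE3": n02 / n_par,
        "BPE4": n06 / n_par,
    }


def tsbpe_features(pe, ser, shell_mask, valid):
    """TSBPE1/TSBPE2: mean PE and mean SER over valid shell voxels."""
    shell_mask = np.asarray(shell_mask, dtype=bool)
    sel = shell_mask & np.asarray(valid, dtype=bool)
    if not sel.any():
        raise ValueError("no valid voxels in the tumor-surrounding shell (TS-BPE stage)")
    return {
        "TSBPE1": float(np.asarray(pe, dtype=float)[sel].mean()),
        "TSBPE2": float(np.asarray(ser, dtype=float)[sel].mean()),
    }


def extract_all(volumes, segs: SegmentationSet, eps=1e-6):
    """All 17 features for one harmonized, segmented case.

    Parameters
    ----------
    volumes
        ``(pre, early, late)`` harmonized volumes on the 1-mm grid.
    segs
        Masks on the same grid.

    Returns
    -------
    dict
        Feature name -> value, in the canonical 17-feature order.
    """
    pre, early, late = volumes
    maps = compute_kinetic_maps(pre, early, late, eps=eps)
    out = {}
    out.update(morphology_features(segs.tumor, early, segs.spacing))
    out.update(glcm_features(maps.ser, segs.tumor, maps.valid))
    out.update(ftv_features(maps.ser, segs.tumor, maps.valid, segs.spacing))
    out.update(bpe_features(maps.pe, segs.parenchyma, maps.valid, segs.spacing))
    out.update(tsbpe_features(maps.pe, maps.ser, segs.shell, maps.valid))
    ordered = {name: out[name] for name in FEATURE_NAMES}
    _validate_feature_vector(ordered)
    return ordered


def _validate_feature_vector(f):
    if not (0 <= f["FTV2"] <= f["FTV1"] <= f["M1"] + 1e-9):
        raise ValueError("expected FTV2 <= FTV1 <= M1")
    if not (0 <= f["BPE2"] <= f["BPE1"] + 1e-9):
        raise ValueError("expected BPE2 <= BPE1")
    if not (0 <= f["BPE4"] <= f["BPE3"] <= 1.0 + 1e-9):
        raise ValueError("expected BPE4 <= BPE3 in [0, 1]")
    if not (0 < f["M2"] <= 1.1):
        raise ValueError("sphericity out of (0, 1.1]")
    if not (0 < f["TEX3"] <= 1.0 + 1e-12):
        raise ValueError("GLCM energy out of (0, 1]")
    if f["TEX4"] < 0 or not (-1.0 - 1e-9 <= f["TEX1"] <= 1.0 + 1e-9):
        raise ValueError("GLCM entropy/correlation out of range")
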