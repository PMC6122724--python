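"""Digital breast DCE-MRI phantoms.

A phantom is a voxel grid with three tissue compartments inside an
ellipsoidal breast — fat, fibroglandular parenchyma and an ellipsoidal
(optionally lobulated) tumor — each with its own contrast kinetics.
Kinetics are specified directly in terms of the two ratio statistics the
feature extractor measures: the percent enhancement PE at the early
post-contrast phase and the signal enhancement ratio SER at the late phase,

    early = pre * (1 + PE),        late = pre + (early - pre) / SER,

so that with zero noise and unit bias field the extractor's PE/SER maps
invert the configured values exactly.  A smooth multiplicative bias field
(exponential of a second-order polynomial) and additive Gaussian noise are
applied on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .core import DCESeries, SegmentationSet
from .segmentation import tumor_shell

# tissue labels in the ground-truth label volume
BACKGROUND, FAT, PARENCHYMA, TUMOR = 0, 1, 2, 3


@dataclass(frozen=True)
class TissueKinetics:
    """Pre-contrast intensity and uptake/washout parameters of one tissue."""

    pre: float     # pre-contrast intensity, arbitrary units
    pe: float      # percent enhancement at the early phase, unitless
    ser: float     # signal enhancement ratio at the late phase, unitless


def _default_kinetics():
    # Non-fat-saturated T1 convention: fat bright with minimal enhancement,
    # parenchyma darker with moderate persistent enhancement, tumor with
    # strong uptake and washout (SER > 1).
    return {
        "fat": TissueKinetics(pre=1000.0, pe=0.05, ser=0.6),
        "parenchyma": TissueKinetics(pre=400.0, pe=0.4, ser=0.8),
        "tumor": TissueKinetics(pre=600.0, pe=1.2, ser=1.3),
    }


@dataclass
class PhantomSpec:
    """Everything needed to build one phantom case deterministically."""

    shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)           # mm per axis
    tumor_semiaxes_mm: tuple = (10.0, 8.0, 6.0)
    tumor_center_mm: tuple | None = None       # default: near breast center
    lobulation_amplitude: float = 0.15         # radial bump, fraction of radius
    parenchyma_fraction: float = 0.25          # of breast volume, in (0, 1)
    kinetics: dict = field(default_factory=_default_kinetics)
    bias_amplitude: float = 0.2                # multiplicative field amplitude
    noise_sd: float = 0.02                     # fraction of parenchyma pre intensity
    acquisition_times: tuple = (0.0, 2.5, 7.5)  # minutes
    shell_distance_mm: float = 20.0
    seed: int = 0
    case_id: str = "phantom"

    def __post_init__(self):
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValueError("tumor semi-axes must be positive")
        if not (0.0 < self.parenchyma_fraction < 1.0):
            raise ValueError("parenchyma fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")


def _grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_radius(coords_mm, center, semiaxes):
    """Normalized ellipsoid coordinate: <= 1 inside."""
    return np.sqrt(sum(((c - c0) / a) ** 2
                       for c, c0, a in zip(coords_mm, center, semiaxes)))


def make_phantom(spec: PhantomSpec):
    """Build one phantom case.

    Returns
    -------
    (series, segs, labels)
        ``series`` is the noisy, bias-modulated :class:`DCESeries` (ground
        truth — clean volumes, bias field, spec — stored in ``series.meta``),
        ``segs`` the ground-truth :class:`SegmentationSet` and ``labels``
        the tissue-label volume (0 background, 1 fat, 2 parenchyma, 3 tumor).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.shape)
    spacing = tuple(float(s) for s in spec.spacing)
    extent = [n * s for n, s in zip(shape, spacing)]
    coords = _grid_mm(shape, spacing)

    breast_center = [e / 2 for e in extent]
    breast_semiaxes = [0.45 * e for e in extent]
    u_breast = _ellipsoid_radius(coords, breast_center, breast_semiaxes)
    breast = u_breast <= 1.0

    # tumor geometry checks: must stay on the grid (named axis) and in breast
    center = (list(spec.tumor_center_mm) if spec.tumor_center_mm is not None
              else [c + 0.1 * a for c, a in zip(breast_center, breast_semiaxes)])
    reach = [a * (1.0 + abs(spec.lobulation_amplitude)) for a in spec.tumor_semiaxes_mm]
    for ax, (c0, r, e) in enumerate(zip(center, reach, extent)):
        if c0 - r < 0 or c0 + r > e:
            raise ValueError(f"tumor geometry exceeds grid along axis {ax}")

    u_tumor = _ellipsoid_radius(coords, center, spec.tumor_semiaxes_mm)
    if spec.lobulation_amplitude != 0.0:
        # low-order angular bump so the surface is lobulated, not ellipsoidal
        dx = [(c - c0) for c, c0 in zip(coords, center)]
        rho = np.sqrt(dx[0] ** 2 + dx[1] ** 2) + 1e-12
        theta = np.arctan2(dx[1], dx[0])
        phi = np.arctan2(rho, dx[2])
        bump = np.sin(3 * theta) * np.cos(2 * phi)
        tumor = u_tumor <= 1.0 + spec.lobulation_amplitude * bump
    else:
        tumor = u_tumor <= 1.0
    if not tumor.any():
        raise ValueError("tumor geometry produced an empty mask")
    if np.any(tumor & ~breast):
        raise ValueError("tumor must lie inside the breast")

    # central fibroglandular region: smoothed noise + centrality, thresholded
    # at the quantile that yields the requested parenchyma fraction; kept
    # interior so hole filling on a fat-only breast mask recovers it
    noise_field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
    noise_field /= max(noise_field[breast].std(), 1e-12)
    centrality = 1.0 - u_breast
    fg_score = np.where(u_breast <= 0.75, centrality + 0.25 * noise_field, -np.inf)
    target = min(spec.parenchyma_fraction, 0.95 * np.isfinite(fg_score[breast]).mean())
    thr = np.quantile(fg_score[breast], 1.0 - target)
    parenchyma = breast & (fg_score >= thr) & ~tumor

    labels = np.zeros(shape, dtype=np.uint8)
    labels[breast] = FAT
    labels[parenchyma] = PARENCHYMA
    labels[tumor] = TUMOR

    # clean kinetic volumes from the per-tissue PE/SER parameters
    pre = np.zeros(shape)
    early = np.zeros(shape)
    late = np.zeros(shape)
    for name, lab in (("fat", FAT), ("parenchyma", PARENCHYMA), ("tumor", TUMOR)):
        k = spec.kinetics[name]
        if k.ser == 0:
            raise ValueError(f"SER for {name} must be nonzero")
        sel = labels == lab
        pre[sel] = k.pre
        early[sel] = k.pre * (1.0 + k.pe)
        late[sel] = k.pre + (k.pre * k.pe) / k.ser
    clean = (pre.copy(), early.copy(), late.copy())

    # smooth multiplicative bias field, mean 1 over the breast
    if spec.bias_amplitude != 0.0:
        norm = [(c - c0) / (0.5 * e) for c, c0, e in zip(coords, breast_center, extent)]
        poly = np.zeros(shape)
        for i in range(3):
            poly += rng.normal() * norm[i]
            for j in range(i, 3):
                poly += rng.normal() * norm[i] * norm[j]
        poly -= poly[breast].mean()
        poly /= max(np.abs(poly[breast]).max(), 1e-12)
        bias = np.exp(spec.bias_amplitude * poly)
        bias /= bias[breast].mean()
    else:
        bias = np.ones(shape)

    sigma = spec.noise_sd * spec.kinetics["parenchyma"].pre
    volumes = []
    for vol in (pre, early, late):
        v = vol * bias
        if sigma > 0:
            v = v + rng.normal(0.0, sigma, size=shape)
        volumes.append(v)

    series = DCESeries(
        volumes=volumes,
        times_min=spec.acquisition_times,
        spacing=spacing,
        case_id=spec.case_id,
        meta={
            "spec": asdict(spec),
            "bias_field": bias,
            "clean_volumes": clean,
            "labels": labels,
        },
    )
    shell = tumor_shell(tumor, parenchyma, spacing=spacing,
                        distance_mm=spec.shell_distance_mm)
    segs = SegmentationSet(breast=breast, tumor=tumor, parenchyma=parenchyma,
                           shell=shell, spacing=spacing)
    return series, segs, labels


def ellipsoid_volume_mm3(semiaxes) -> float:
    """Analytic ellipsoid volume, for ground-truth checks."""
    a, b, c = semiaxes
    return 4.0 / 3.0 * math.pi * a * b * c
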