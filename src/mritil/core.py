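"""Shared containers for DCE-MRI cases.

A *case* is one breast DCE-MRI exam: a time-ordered stack of 3-D volumes
(pre-contrast plus post-contrast phases) with a common voxel grid, together
with binary masks of the anatomical compartments the features are computed
over (whole breast, tumor, fibroglandular parenchyma, and the 2-cm
peritumoral shell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical order of the 17 imaging features: five tumor morphology
#: features (M), four SER-map texture features (TEX), two functional tumor
#: volumes (FTV), four background parenchymal enhancement features (BPE)
#: and two tumor-surrounding BPE features (TS-BPE).
FEATURE_NAMES = [
    "M1", "M2", "M3", "M4", "M5",
    "TEX1", "TEX2", "TEX3", "TEX4",
    "FTV1", "FTV2",
    "BPE1", "BPE2", "BPE3", "BPE4",
    "TSBPE1", "TSBPE2",
]


@dataclass
class DCESeries:
    """One dynamic contrast-enhanced series.

    Parameters
    ----------
    volumes
        Time-ordered 3-D intensity volumes; the first is pre-contrast.
    times_min
        Acquisition time offsets in minutes; the first must be 0.
    spacing
        Voxel spacing in mm per axis.
    case_id
        Identifier carried through to feature tables.
    meta
        Free-form provenance (phantoms stash ground truth here).
    """

    volumes: list
    times_min: tuple
    spacing: tuple
    case_id: str = "case"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volumes = [np.asarray(v, dtype=float) for v in self.volumes]
        self.times_min = tuple(float(t) for t in self.times_min)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.volumes) < 3:
            raise ValueError("a DCE series needs >= 3 volumes (pre + 2 post-contrast)")
        if len(self.times_min) != len(self.volumes):
            raise ValueError("one acquisition time per volume required")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("acquisition times must be strictly increasing")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError("all volumes must share one grid")
        if len(self.spacing) != self.volumes[0].ndim:
            raise ValueError("spacing must give one value per axis")

    @property
    def shape(self):
        return self.volumes[0].shape


@dataclass
class SegmentationSet:
    """Binary masks for one case on a common grid."""

    breast: np.ndarray
    tumor: np.ndarray
    parenchyma: np.ndarray
    shell: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.breast = np.asarray(self.breast, dtype=bool)
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.parenchyma = np.asarray(self.parenchyma, dtype=bool)
        self.shell = np.asarray(self.shell, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        shapes = {m.shape for m in (self.breast, self.tumor, self.parenchyma, self.shell)}
        if len(shapes) != 1:
            raise ValueError("all masks must share one grid")
        self.validate()

    def validate(self):
        if np.any(self.parenchyma & ~self.breast):
            raise ValueError("parenchyma must be contained in the breast mask")
        if np.any(self.tumor & self.parenchyma):
            raise ValueError("tumor and parenchyma must be disjoint")
        if np.any(self.shell & ~self.breast):
            raise ValueError("shell must be contained in the breast mask")
        if np.any(self.shell & self.tumor):
            raise ValueError("shell and tumor must be disjoint")


@dataclass
class KineticMaps:
    """Voxelwise percent enhancement (PE) and signal enhancement ratio (SER).

    ``valid`` marks voxels where both ratio denominators are usable
    (pre-contrast intensity above epsilon for PE; |late - pre| above
    epsilon for SER).
    """

    pe: np.ndarray
    ser: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.pe = np.asarray(self.pe, dtype=float)
        self.ser = np.asarray(self.ser, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.pe.shape == self.ser.shape == self.valid.shape):
            raise ValueError("PE, SER and validity mask must share one grid")
        if not np.all(np.isfinite(self.pe[self.valid])):
            raise ValueError("PE must be finite on the validity mask")
        if not np.all(np.isfinite(self.ser[self.valid])):
            raise ValueError("SER must be finite on the validity mask")


def voxel_volume_mm3(spacing) -> float:
    return float(np.prod(spacing))
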