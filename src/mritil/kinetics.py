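"""Voxelwise kinetic maps.

PE (percent enhancement) and SER (signal enhancement ratio) summarize the
uptake-washout behaviour of each voxel across the three harmonized phases:

    PE  = (early - pre) / pre
    SER = (early - pre) / (late - pre)

SER > 1 indicates washout (early enhancement exceeding late), the kinetic
pattern associated with malignancy; PE measures early uptake amplitude.
Voxels whose denominator magnitude is below epsilon are flagged invalid
rather than raising.
"""

from __future__ import annotations

import numpy as np

from .core import KineticMaps

EPS = 1e-6


def _check_grids(*volumes):
    shapes = {np.asarray(v).shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError("volumes must share one grid")


def compute_pe(pre, early, eps=EPS):
    """PE map and its validity mask (pre-contrast intensity > eps)."""
    _check_grids(pre, early)
    pre = np.asarray(pre, dtype=float)
    early = np.asarray(early, dtype=float)
    valid = pre > eps
    pe = np.full(pre.shape, np.nan)
    np.divide(early - pre, pre, out=pe, where=valid)
    return pe, valid


def compute_ser(pre, early, late, eps=EPS):
    """SER map and its validity mask (|late - pre| > eps)."""
    _check_grids(pre, early, late)
    pre = np.asarray(pre, dtype=float)
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    denom = late - pre
    valid = np.abs(denom) > eps
    ser = np.full(pre.shape, np.nan)
    np.divide(early - pre, denom, out=ser, where=valid)
    return ser, valid


def compute_kinetic_maps(pre, early, late, eps=EPS) -> KineticMaps:
    """Both maps with the joint validity mask (both denominators usable)."""
    pe, v1 = compute_pe(pre, early, eps=eps)
    ser, v2 = compute_ser(pre, early, late, eps=eps)
    return KineticMaps(pe=pe, ser=ser, valid=v1 & v2)
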