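"""End-to-end per-case processing: raw series + tumor mask -> 17 features.

Order of operations (fixed): breast masking on the raw pre-contrast
volume, bias correction (field estimated once on the pre-contrast volume
and divided out of every phase, since receive-coil shading is common to
the dynamic series), phase standardization, fuzzy c-means parenchyma
segmentation, interquartile-parenchyma intensity normalization, 1-mm
isotropic resampling, 2-cm peritumoral shell construction, feature
extraction.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .core import DCESeries, SegmentationSet
from . import preprocess, segmentation
from .features import extract_all


class CaseResult(NamedTuple):
    features: dict
    segs: SegmentationSet
    volumes: tuple          # harmonized (pre, early, late) at 1 mm
    provenance: dict


def process_case(series: DCESeries, tumor_mask, fat_sat=False,
                 shell_distance_mm=20.0, fcm_seed=0) -> CaseResult:
    """Run the full harmonization + segmentation + extraction chain."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if tumor_mask.shape != series.shape:
        raise ValueError("tumor mask must be on the series grid")

    pre_raw = series.volumes[0]
    breast = segmentation.make_breast_mask(pre_raw)

    bias = preprocess.correct_bias(pre_raw, breast)
    corrected = DCESeries(
        volumes=[v / bias.field for v in series.volumes],
        times_min=series.times_min, spacing=series.spacing,
        case_id=series.case_id)

    phases = preprocess.select_phases(corrected)

    parenchyma = segmentation.fcm_parenchyma(
        phases.pre, breast, tumor_mask, fat_sat=fat_sat, seed=fcm_seed)
    norm = preprocess.normalize_intensity(
        (phases.pre, phases.early, phases.late), parenchyma)

    vols_iso = []
    for v in norm.volumes:
        iso, spacing_iso = preprocess.resample_isotropic(v, series.spacing)
        vols_iso.append(iso)
    masks_iso = {}
    for name, m in (("breast", breast), ("tumor", tumor_mask),
                    ("parenchyma", parenchyma)):
        masks_iso[name], _ = preprocess.resample_isotropic(
            m, series.spacing, is_mask=True)

    shell = segmentation.tumor_shell(
        masks_iso["tumor"], masks_iso["parenchyma"], spacing=spacing_iso,
        distance_mm=shell_distance_mm)
    segs = SegmentationSet(breast=masks_iso["breast"], tumor=masks_iso["tumor"],
                           parenchyma=masks_iso["parenchyma"], shell=shell,
                           spacing=spacing_iso)

    features = extract_all(tuple(vols_iso), segs)
    provenance = {
        "case_id": series.case_id,
        "phase_times_min": phases.times,
        "normalization_reference": norm.reference,
        "bias_coefficients": bias.coefficients.tolist(),
    }
    return CaseResult(features=features, segs=segs, volumes=tuple(vols_iso),
                      provenance=provenance)
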