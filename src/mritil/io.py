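"""NIfTI and table I/O for phantom cases."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DCESeries, SegmentationSet

_PHASES = ("pre", "early", "late")
_MASKS = ("breast", "tumor", "parenchyma", "shell")


def _affine(spacing):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_case(case_dir, series: DCESeries, segs: SegmentationSet | None = None):
    """Write one case as .nii.gz volumes plus a JSON sidecar."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.spacing)
    for name, vol in zip(_PHASES, series.volumes):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                 case_dir / f"{name}.nii.gz")
    if segs is not None:
        for name in _MASKS:
            m = getattr(segs, name)
            nib.save(nib.Nifti1Image(m.astype(np.uint8), aff),
                     case_dir / f"mask_{name}.nii.gz")
    sidecar = {
        "case_id": series.case_id,
        "times_min": list(series.times_min),
        "spacing": list(series.spacing),
    }
    spec = series.meta.get("spec")
    if spec is not None:
        sidecar["spec"] = spec if isinstance(spec, dict) else asdict(spec)
        sidecar["spec"]["kinetics"] = {
            k: (asdict(v) if not isinstance(v, dict) else v)
            for k, v in sidecar["spec"]["kinetics"].items()}
    (case_dir / "case.json").write_text(json.dumps(sidecar, indent=2))


def load_case(case_dir):
    """Read a case written by :func:`save_case`.

    Returns ``(series, segs_or_None)``.
    """
    case_dir = Path(case_dir)
    sidecar = json.loads((case_dir / "case.json").read_text())
    volumes = [np.asarray(nib.load(case_dir / f"{p}.nii.gz").dataobj, dtype=float)
               for p in _PHASES]
    series = DCESeries(volumes=volumes, times_min=tuple(sidecar["times_min"]),
                       spacing=tuple(sidecar["spacing"]),
                       case_id=sidecar["case_id"], meta={"spec": sidecar.get("spec")})
    segs = None
    if (case_dir / "mask_breast.nii.gz").exists():
        masks = {m: np.asarray(nib.load(case_dir / f"mask_{m}.nii.gz").dataobj) > 0
                 for m in _MASKS}
        segs = SegmentationSet(spacing=tuple(sidecar["spacing"]), **masks)
    return series, segs
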