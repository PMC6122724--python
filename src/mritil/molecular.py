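"""Immune-related molecular features.

Two per-case quantities are used alongside the imaging features:

* the cytolytic activity score — the geometric mean of the expression of
  the two cytolytic effector genes granzyme A (GZMA) and perforin (PRF1),
  a transcript-level proxy for local immune effector activity;
* the nonsynonymous somatic mutation burden — the count of
  protein-altering somatic variants (missense, nonsense, frameshift,
  splice), a proxy for neoantigen load.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Closed vocabulary of variant effect classes.
EFFECT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "silent", "other"})

#: Effect classes counted as protein-altering.
NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift", "splice"})

#: Mapping from MAF-style Variant_Classification strings to the vocabulary.
MAF_CLASSIFICATION = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Silent": "silent",
    "In_Frame_Del": "other",
    "In_Frame_Ins": "other",
    "Translation_Start_Site": "other",
    "3'UTR": "other",
    "5'UTR": "other",
    "Intron": "other",
    "RNA": "other",
    "IGR": "other",
}


def cytolytic_score(gzma, prf1):
    """Geometric mean of GZMA and PRF1 expression.

    Both inputs must be strictly positive (no silent pseudocounting);
    scalars or arrays are accepted.
    """
    g = np.asarray(gzma, dtype=float)
    p = np.asarray(prf1, dtype=float)
    if np.any(g <= 0) or np.any(p <= 0):
        raise ValueError("expression values must be strictly positive")
    score = np.sqrt(g * p)
    return float(score) if score.ndim == 0 else score


def mutation_burden(variants) -> int:
    """Count of nonsynonymous somatic variants for one case.

    ``variants`` is an iterable of records with ``effect`` and ``somatic``
    fields (dicts, namedtuples/objects, or a DataFrame with those columns).
    Counted effects: missense, nonsense, frameshift, splice; silent and
    other are excluded, as are non-somatic records.
    """
    if isinstance(variants, pd.DataFrame):
        records = variants.to_dict("records")
    else:
        records = list(variants)
    count = 0
    for rec in records:
        if isinstance(rec, dict):
            effect, somatic = rec["effect"], rec["somatic"]
        else:
            effect, somatic = rec.effect, rec.somatic
        if effect not in EFFECT_CLASSES:
            raise ValueError(
                f"unknown variant effect class {effect!r}; expected one of "
                f"{sorted(EFFECT_CLASSES)}")
        if somatic and effect in NONSYNONYMOUS:
            count += 1
    return count


def burden_from_maf(maf: pd.DataFrame, case_column="Tumor_Sample_Barcode") -> pd.Series:
    """Per-case nonsynonymous burden from a simplified MAF-like table.

    Expects ``Variant_Classification`` (mapped through
    :data:`MAF_CLASSIFICATION`) and a case-identifier column; all rows are
    treated as somatic, as in a somatic MAF.
    """
    effects = maf["Variant_Classification"].map(MAF_CLASSIFICATION)
    if effects.isna().any():
        bad = sorted(maf.loc[effects.isna(), "Variant_Classification"].unique())
        raise ValueError(f"unmapped Variant_Classification values: {bad}")
    keep = effects.isin(NONSYNONYMOUS)
    return maf.loc[keep].groupby(case_column).size().rename("mutation_burden")
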