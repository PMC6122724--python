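"""Synthetic cohorts with the statistical structure the analysis assumes.

Each case carries the 17 imaging features, a pathology-style TIL
percentage, GZMA/PRF1 expression, a nonsynonymous mutation count, receptor
status and a recurrence-free-survival record.  The generative chain:

* features are affine transforms of independent standard-normal latents at
  plausible raw scales;
* the latent TIL score is a linear combination of designated standardized
  features plus Gaussian noise, clipped to [0, 90] for the recorded
  percentage (matching the ceiling of the high category);
* log cytolytic activity is coupled to the latent TIL score by a Gaussian
  copula at a target correlation; GZMA and PRF1 are log-normal with their
  geometric mean equal to the cytolytic latent;
* mutation counts are Poisson-log-normal, weakly coupled to TILs;
* recurrence times are exponential with administrative censoring; inside
  the TNBC-like (HR-/HER2-) subgroup the no/minimal-TIL group carries a
  configurable hazard ratio, elsewhere the baseline hazard applies.

Defaults state the world the analysis expects: the designated features and
true weights are the five published signature terms and coefficients, and
the cytolytic-TIL correlation is the reported 0.51.  The latent intercept
(16) and TIL noise SD (2 percentage points) are set so the generator's own
contract holds: clipping at 0 stays rare enough (< 1% of cases) that
regressing generated TILs on the generating features recovers the true
weights within 3 standard errors, and the weakest designated weight (0.72)
stays identifiable (~8 SE at n = 500) for stability selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES
from .phantom import PhantomSpec
from .signature import categorize_til

#: plausible raw scales (mean, SD) per feature; volumes in mm^3
FEATURE_SCALES = {
    "M1": (5000.0, 2000.0), "M2": (0.8, 0.1), "M3": (0.9, 0.3),
    "M4": (0.5, 0.2), "M5": (0.2, 0.08),
    "TEX1": (0.3, 0.2), "TEX2": (0.0, 5.0), "TEX3": (0.1, 0.05),
    "TEX4": (4.0, 1.0),
    "FTV1": (2500.0, 1200.0), "FTV2": (1000.0, 600.0),
    "BPE1": (30000.0, 15000.0), "BPE2": (8000.0, 5000.0),
    "BPE3": (0.4, 0.15), "BPE4": (0.1, 0.06),
    "TSBPE1": (0.5, 0.2), "TSBPE2": (0.9, 0.3),
}


def _default_weights():
    # the five published signature terms and their printed coefficients
    return {"M1": 4.4, "TEX2": -3.14, "TSBPE2": -2.0, "BPE1": -2.62,
            "BPE3": -0.72}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n: int = 126
    true_weights: dict = field(default_factory=_default_weights)
    til_intercept: float = 16.0
    til_noise_sd: float = 2.0
    cytolytic_til_corr: float = 0.51
    tnbc_fraction: float = 0.4
    baseline_hazard: float = 0.02          # events per month
    til_group_hazard_ratio: float = 2.0    # no/minimal vs rest, within TNBC
    censoring_months: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 cases")
        if not -1.0 <= self.cytolytic_til_corr <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")
        if self.baseline_hazard <= 0 or self.til_group_hazard_ratio <= 0:
            raise ValueError("hazards must be positive")
        if self.til_noise_sd < 0:
            raise ValueError("TIL noise SD must be non-negative")
        if not 0.0 <= self.tnbc_fraction <= 1.0:
            raise ValueError("TNBC fraction must lie in [0, 1]")
        unknown = set(self.true_weights) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in true_weights: {sorted(unknown)}")


def make_cohort(spec: CohortSpec):
    """Generate a cohort table and matching per-case phantom specs.

    Returns ``(phantom_specs, table)``.  The phantom specs are cheap case
    descriptors (one per row, tumor size matched to the sampled M1);
    materialize any of them with :func:`mritil.make_phantom`.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    z = rng.standard_normal((n, len(FEATURE_NAMES)))
    means = np.array([FEATURE_SCALES[f][0] for f in FEATURE_NAMES])
    sds = np.array([FEATURE_SCALES[f][1] for f in FEATURE_NAMES])
    features = means + sds * z

    w = np.array([spec.true_weights.get(f, 0.0) for f in FEATURE_NAMES])
    latent = spec.til_intercept + z @ w + rng.normal(0.0, spec.til_noise_sd, n)
    til = np.clip(latent, 0.0, 90.0)

    # Gaussian copula: log cytolytic activity tracks the standardized latent
    u = (latent - latent.mean()) / max(latent.std(ddof=1), 1e-12)
    rho = spec.cytolytic_til_corr
    c = rho * u + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal(n)
    log_cyt = np.log(50.0) + 0.4 * c
    split = rng.normal(0.0, 0.3, n)  # gene-level wobble; geometric mean unaffected
    gzma = np.exp(log_cyt + split)
    prf1 = np.exp(log_cyt - split)

    mut_latent = 0.13 * u + np.sqrt(1 - 0.13 ** 2) * rng.standard_normal(n)
    mutations = rng.poisson(np.exp(np.log(40.0) + 0.5 * mut_latent))

    tnbc = rng.random(n) < spec.tnbc_fraction
    her2 = ~tnbc & (rng.random(n) < 0.3)
    hr_pos = ~tnbc & ~her2

    til_group = categorize_til(til)
    low = til_group == "no/minimal"
    hazard = np.full(n, spec.baseline_hazard)
    hazard[tnbc & low] *= spec.til_group_hazard_ratio
    raw_times = rng.exponential(1.0 / hazard)
    event = raw_times <= spec.censoring_months
    rfs = np.minimum(raw_times, spec.censoring_months)

    table = pd.DataFrame(features, columns=FEATURE_NAMES)
    table.insert(0, "case_id", [f"case{i:04d}" for i in range(n)])
    table["TIL"] = til
    table["til_group"] = til_group
    table["GZMA"] = gzma
    table["PRF1"] = prf1
    table["mutation_count"] = mutations
    table["HR_status"] = hr_pos.astype(int)
    table["HER2_status"] = her2.astype(int)
    table["TNBC"] = tnbc.astype(int)
    table["rfs_months"] = rfs
    table["rfs_event"] = event.astype(int)

    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    phantom_specs = []
    for i in range(n):
        vol = max(float(features[i, FEATURE_NAMES.index("M1")]), 500.0)
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        phantom_specs.append(PhantomSpec(
            tumor_semiaxes_mm=(min(1.2 * r, 13.0), min(r, 13.0), min(r / 1.2, 13.0)),
            seed=int(child_seeds[i]),
            case_id=table.loc[i, "case_id"],
        ))
    return phantom_specs, table
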