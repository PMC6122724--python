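"""Fit the imaging signature and the composite TIL model.

Standardizes the 17 discovery-cohort features, runs LASSO stability
selection (tenfold CV repeated 100 times, one-standard-error penalty,
selection frequency > 90%), refits the retained features by OLS, then
combines the signature prediction with the z-scored cytolytic score into a
composite linear model.  Models are serialized as JSON; correlations of
each predictor with pathology TILs are printed.
"""

import argparse
from pathlib import Path

import pandas as pd

from mritil.cohort import CohortSpec, make_cohort
from mritil.core import FEATURE_NAMES
from mritil.evaluation import pearson_ci
from mritil.molecular import cytolytic_score
from mritil.signature import SignatureModel, fit_linear, lasso_select, standardize

RESULTS = Path(__file__).resolve().parents[1] / "results"


def fit_models(tab, seed):
    z, means, sds = standardize(tab[FEATURE_NAMES])
    y = tab.TIL.to_numpy()
    report = lasso_select(z, y, folds=10, repeats=100, threshold=0.9,
                          seed=seed, one_se=True)
    imaging = fit_linear(z[report.selected], y)
    imaging.means = means[report.selected].to_numpy()
    imaging.sds = sds[report.selected].to_numpy()

    sig_pred = imaging.predict(tab[report.selected])
    cyt = cytolytic_score(tab.GZMA, tab.PRF1)
    comp_in = pd.DataFrame({"imaging_signature": sig_pred, "cytolytic_score": cyt})
    z_comp, m_comp, s_comp = standardize(comp_in)
    composite = fit_linear(z_comp, y)
    composite.means = m_comp.to_numpy()
    composite.sds = s_comp.to_numpy()
    return report, imaging, composite, sig_pred, cyt


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    _, tab = make_cohort(CohortSpec(n=126, seed=args.seed))
    report, imaging, composite, sig_pred, cyt = fit_models(tab, args.seed)

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame({"feature": report.feature_names,
                  "selection_frequency": report.frequencies}).to_csv(
        RESULTS / "selection_frequencies.csv", index=False)
    imaging.to_json(RESULTS / "imaging_signature.json")
    composite.to_json(RESULTS / "composite_model.json")

    terms = " + ".join(f"{c:.2f}*z({f})" for f, c
                       in zip(imaging.feature_names, imaging.coefficients))
    print(f"selected features (>90% of repeats): {report.selected}")
    print(f"imaging signature: TIL ~ {terms} + {imaging.intercept:.2f}")

    comp_pred = composite.predict(pd.DataFrame(
        {"imaging_signature": sig_pred, "cytolytic_score": cyt}))
    for name, pred in (("imaging signature", sig_pred),
                       ("cytolytic score", cyt),
                       ("composite model", comp_pred)):
        rho, ci, p = pearson_ci(pred, tab.TIL)
        print(f"rho({name}, TILs) = {rho:.2f} (95% CI {ci[0]:.2f}-{ci[1]:.2f}, "
              f"p = {p:.2g})")


if __name__ == "__main__":
    main()
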