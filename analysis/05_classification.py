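"""Pairwise classification of TIL categories.

For every pair of TIL categories present in the discovery cohort, evaluates
the imaging signature, the cytolytic score and the composite model as
binary classifiers: AUC, the Youden operating point (sensitivity,
specificity, accuracy), the Mann-Whitney test against chance, and the
DeLong comparison of composite vs cytolytic AUCs.

Under the generator's linear-Gaussian TIL model the high category (> 40%)
is essentially absent at n = 126, so typically only the no/minimal vs
intermediate pair is populated; the loop covers whichever pairs exist.
"""

import argparse
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from mritil.cohort import CohortSpec, make_cohort
from mritil.evaluation import delong_test, mann_whitney, roc_with_youden
from mritil.molecular import cytolytic_score
from mritil.signature import TIL_CATEGORIES

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "fit_signature", Path(__file__).with_name("04_fit_signature.py"))
_fit = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_fit)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    _, tab = make_cohort(CohortSpec(n=126, seed=args.seed))
    _, imaging, composite, sig_pred, cyt = _fit.fit_models(tab, args.seed)
    comp_pred = composite.predict(pd.DataFrame(
        {"imaging_signature": sig_pred, "cytolytic_score": cyt}))
    predictors = {"imaging_signature": np.asarray(sig_pred),
                  "cytolytic_score": np.asarray(cyt),
                  "composite": np.asarray(comp_pred)}

    rows = []
    for lo, hi in combinations(TIL_CATEGORIES, 2):
        sel = tab.til_group.isin([lo, hi]).to_numpy()
        labels = (tab.til_group[sel] == hi).to_numpy().astype(int)
        if labels.sum() < 2 or (1 - labels).sum() < 2:
            print(f"{lo} vs {hi}: skipped (category too small in this cohort)")
            continue
        for name, scores in predictors.items():
            r = roc_with_youden(scores[sel], labels)
            _, p_chance = mann_whitney(scores[sel][labels == 1],
                                       scores[sel][labels == 0])
            rows.append({"pair": f"{lo} vs {hi}", "model": name, "auc": r.auc,
                         "sensitivity": r.youden_sensitivity,
                         "specificity": r.youden_specificity,
                         "accuracy": r.youden_accuracy, "p_vs_chance": p_chance})
        d, ci, p = delong_test(predictors["composite"][sel],
                               predictors["cytolytic_score"][sel], labels)
        print(f"{lo} vs {hi}: composite - cytolytic AUC = {d:+.3f} "
              f"(95% CI {ci[0]:.3f} to {ci[1]:.3f}, DeLong p = {p:.3f})")

    out = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "classification.csv", index=False)
    if len(out):
        print(out.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
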