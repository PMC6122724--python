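"""Statistical evaluation of TIL models.

Correlation with Fisher-z confidence intervals, Benjamini-Hochberg FDR,
ROC analysis with the Youden operating point, the DeLong test for paired
AUCs, the Mann-Whitney U test, ICC(2,1) agreement, Kaplan-Meier /
log-rank survival comparison and Harrell's concordance index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    youden_accuracy: float


@dataclass
class SurvivalResult:
    """Two-group Kaplan-Meier comparison."""

    curves: dict          # group -> dict(time, survival, at_risk)
    logrank_statistic: float
    logrank_p: float
    concordance: float | None = None


def pearson_ci(x, y, alpha=0.05):
    """Pearson correlation with Fisher-z CI and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    rho, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return float(rho), ci, float(p)


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_with_youden(scores, labels) -> ROCResult:
    """Empirical ROC, trapezoidal AUC and the Youden operating point.

    Positives are scores >= threshold.  The Youden threshold maximizes
    sensitivity + specificity - 1; ties break toward higher specificity
    (i.e. the higher threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    j = sens + spec - 1.0
    finite = np.isfinite(thresholds)
    jf = np.where(finite, j, -np.inf)
    best_j = jf.max()
    # among maximizers, the largest threshold gives the highest specificity
    candidates = np.flatnonzero(jf >= best_j - 1e-12)
    best = candidates[np.argmax(thresholds[candidates])]
    t = float(thresholds[best])
    tp = (scores[labels] >= t).sum()
    tn = (scores[~labels] < t).sum()
    accuracy = float((tp + tn) / (n_pos + n_neg))
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc,
        youden_threshold=t, youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]), youden_accuracy=accuracy)


def _placements(pos, neg):
    """DeLong placement values via midranks."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    order = stats.rankdata(allv)  # midranks
    rank_pos = order[:m]
    rank_neg = order[m:]
    auc = (rank_pos.sum() - m * (m + 1) / 2) / (m * n)
    v10 = (rank_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (rank_neg - stats.rankdata(neg)) / m
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels, alpha=0.05):
    """DeLong comparison of two paired AUCs.

    Returns ``(auc_difference, (ci_low, ci_high), p_value)`` with the
    normal-approximation two-sided p-value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    aucs, v10s, v01s = [], [], []
    for s in (scores_a, scores_b):
        auc, v10, v01 = _placements(s[labels], s[~labels])
        aucs.append(auc)
        v10s.append(v10)
        v01s.append(v01)
    m = int(labels.sum())
    n = int((~labels).sum())
    s10 = np.cov(np.vstack(v10s)) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack(v01s)) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
        return float(diff), (float(diff), float(diff)), p
    se = np.sqrt(var)
    z = diff / se
    p = 2 * stats.norm.sf(abs(z))
    half = stats.norm.ppf(1 - alpha / 2) * se
    return float(diff), (float(diff - half), float(diff + half)), float(p)


def mann_whitney(group1, group2):
    """Two-sided Mann-Whitney U; exact when n1 + n2 <= 12 and tie-free."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    exact = g1.size + g2.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def icc(table):
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a cases x raters table")
    n, k = table.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 cases and >= 2 raters")
    if np.any(~np.isfinite(table)):
        raise ValueError("table contains missing values")
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 0.0
    return float((msr - mse) / denom)


def km_logrank(times, events, groups, risk_scores=None) -> SurvivalResult:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    At tied times events precede censorings (risk-set convention).  When
    ``risk_scores`` are supplied, Harrell's concordance index is included.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups are required for the log-rank test")
    if not events.any():
        raise ValueError("no events observed")

    curves = {}
    for g in labels:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        curves[g] = {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].to_numpy(),
        }
    sel = groups == labels[0]
    res = logrank_test(times[sel], times[~sel], events[sel], events[~sel])
    c = None
    if risk_scores is not None:
        c = concordance_index(risk_scores, times, events)
    return SurvivalResult(curves=curves,
                          logrank_statistic=float(res.test_statistic),
                          logrank_p=float(res.p_value), concordance=c)


def concordance_index(risk_scores, times, events):
    """Harrell's C: concordance of risk with event ordering.

    Usable pairs are those where the shorter observed time ends in an
    event; the pair is concordant when that subject also has the higher
    risk; risk ties count 0.5.
    """
    risk = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    n = times.size
    concordant = 0.0
    usable = 0
    for i in range(n):
        if not events[i]:
            continue
        comparable = times > times[i]
        usable += int(comparable.sum())
        concordant += (risk[comparable] < risk[i]).sum()
        concordant += 0.5 * (risk[comparable] == risk[i]).sum()
    if usable == 0:
        raise ValueError("no comparable pairs")
    return float(concordant / usable)
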