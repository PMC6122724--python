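"""Evaluation statistics against brute-force and cross-library oracles."""

import numpy as np
import pytest
from scipy import stats

from mritil.evaluation import (pearson_ci, bh_fdr, roc_with_youden, delong_test,
                               mann_whitney, icc, km_logrank, concordance_index)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        rho, ci, p = pearson_ci(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        # independent arithmetic: covariance ratio
        want = (((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        rho, ci, p = pearson_ci(x, y)
        assert rho == pytest.approx(want, rel=1e-12)
        assert ci[0] < rho < ci[1]

    def test_small_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])


def bh_oracle(p):
    """Step-up rule by explicit enumeration over all ranks."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        candidates = [m * p[j] / (list(order).index(j) + 1)
                      for j in order[rank_idx:]]
        q[i] = min(1.0, min(candidates))
    return q


class TestBHFDR:
    def test_matches_bruteforce_on_spec_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_on_random(self, seed):
        p = np.random.default_rng(seed).random(12)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_degenerate_inputs(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_permutation_invariance(self, rng):
        p = rng.random(9)
        perm = rng.permutation(9)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)


def auc_pair_oracle(scores, labels):
    """Concordant/discordant/tied pair counting."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc_with_youden(np.array([1, 2, 3, 10, 11, 12.0]),
                            np.array([0, 0, 0, 1, 1, 1]))
        assert r.auc == 1.0 and r.youden_accuracy == 1.0

    def test_identical_scores_auc_half(self):
        r = roc_with_youden(np.ones(8), np.array([0, 1] * 4))
        assert r.auc == pytest.approx(0.5)

    def test_six_point_toy_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.8, 0.2])
        labels = np.array([0, 0, 1, 1, 0, 1])
        r = roc_with_youden(scores, labels)
        assert r.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trapezoid_equals_u_statistic(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, 40).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        r = roc_with_youden(scores, labels)
        assert r.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    def test_youden_tie_breaks_toward_higher_specificity(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        r = roc_with_youden(scores, labels)
        # J = 0.5 at thresholds 4 and 2; the higher threshold has spec 1.0
        assert r.youden_threshold == 4.0 and r.youden_specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_youden(np.arange(4.0), np.ones(4))


class TestDeLong:
    def test_equal_scores_null(self, rng):
        s = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        diff, ci, p = delong_test(s, s, labels)
        assert diff == 0.0 and p == 1.0

    def test_variance_matches_paired_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 120
        labels = np.concatenate([np.ones(60), np.zeros(60)]).astype(int)
        latent = rng.normal(size=n) + labels
        a = latent + rng.normal(0, 0.8, n)
        b = latent + rng.normal(0, 1.2, n)
        diff, ci, p = delong_test(a, b, labels)
        se = (ci[1] - ci[0]) / (2 * stats.norm.ppf(0.975))
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            la = labels[idx]
            if la.all() or not la.any():
                continue
            boots.append(auc_pair_oracle(a[idx], la) - auc_pair_oracle(b[idx], la))
        assert np.std(boots, ddof=1) == pytest.approx(se, rel=0.15)

    def test_null_p_values_uniform(self):
        """Under exchangeable scores the DeLong p-value is ~uniform
        (Kolmogorov distance < 0.1 over 200 replicates)."""
        rng = np.random.default_rng(0)
        pvals = []
        labels = np.concatenate([np.ones(50), np.zeros(50)]).astype(int)
        for _ in range(200):
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            pvals.append(delong_test(a, b, labels)[2])
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_test(np.arange(4.0), np.arange(4.0), np.zeros(4))


class TestMannWhitney:
    def test_full_separation_gives_max_u(self):
        u, p = mann_whitney([5.0, 6.0, 7.0], [1.0, 2.0])
        assert u == 6.0  # n1*n2

    def test_identical_groups(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_exact_enumeration_toy(self):
        # all 20 arrangements of (1,2,3) vs (4,5,6): two-sided exact p = 0.1
        u, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestICC:
    def test_perfect_agreement(self, rng):
        x = rng.normal(size=10)
        assert icc(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_constant_shift_penalized(self, rng):
        x = rng.normal(size=10)
        assert icc(np.column_stack([x, x + 2.0])) < 1.0

    def test_hand_computed_anova_toy(self):
        table = np.array([[9.0, 2.0], [4.5, 4.0], [5.0, 4.5],
                          [8.0, 7.0], [9.5, 8.0], [6.0, 5.5]])
        n, k = table.shape
        grand = table.mean()
        msr = k * ((table.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((table.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((table - table.mean(1, keepdims=True)
                 - table.mean(0, keepdims=True) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        want = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(table) == pytest.approx(want, rel=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        table = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1))
        long = pd.DataFrame({
            "case": np.repeat(np.arange(8), 2),
            "rater": np.tile([0, 1], 8),
            "value": table.ravel()})
        ref = pingouin.intraclass_corr(long, targets="case", raters="rater",
                                       ratings="value")
        # two-way random, absolute agreement, single rater: ICC(A,1) == ICC(2,1)
        sel = ref.Type.isin(["ICC(A,1)", "ICC2"])
        want = ref.loc[sel, "ICC"].iloc[0]
        assert icc(table) == pytest.approx(want, rel=1e-9)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc(np.ones((2, 2)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


class TestSurvival:
    def test_km_equals_empirical_without_censoring(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.ones(6, dtype=int)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = km_logrank(times, events, groups)
        surv = res.curves["a"]["survival"]
        np.testing.assert_allclose(surv, [1.0, 2 / 3, 1 / 3, 0.0])

    def test_identical_groups_null(self):
        times = np.tile([2.0, 4.0, 6.0, 8.0], 2)
        events = np.ones(8, dtype=int)
        groups = np.repeat(["a", "b"], 4)
        res = km_logrank(times, events, groups)
        assert res.logrank_p >= 0.99

    def test_eight_subject_worked_example(self):
        """Observed-minus-expected and variance terms recomputed from
        explicit risk tables; chi-square must match."""
        times = np.array([1.0, 2, 3, 4, 2, 4, 5, 6])
        events = np.array([1, 1, 1, 0, 1, 1, 1, 0])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(set(times[events == 1])):
            at_risk = times >= t
            d = ((times == t) & (events == 1)).sum()
            n = at_risk.sum()
            n_a = (at_risk & (groups == "a")).sum()
            d_a = ((times == t) & (events == 1) & (groups == "a")).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        chi2 = o_minus_e ** 2 / var
        res = km_logrank(times, events, groups)
        assert res.logrank_statistic == pytest.approx(chi2, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [0, 0], ["a", "b"])


class TestConcordance:
    def test_perfect_ordering(self):
        times = np.array([5.0, 4, 3, 2, 1])
        risk = np.array([1.0, 2, 3, 4, 5])  # shorter time <-> higher risk
        assert concordance_index(risk, times, np.ones(5, dtype=int)) == 1.0

    def test_random_risk_near_half(self, rng):
        n = 400
        times = rng.exponential(10, n)
        events = rng.random(n) < 0.8
        risk = rng.normal(size=n)
        c = concordance_index(risk, times, events)
        assert 0.45 < c < 0.55

    def test_five_subject_toy_matches_enumeration(self):
        times = np.array([1.0, 2, 3, 4, 5])
        events = np.array([1, 1, 0, 1, 1])
        risk = np.array([5.0, 3, 4, 4, 1])
        conc = 0.0
        usable = 0
        for i in range(5):
            for j in range(5):
                if events[i] and times[i] < times[j]:
                    usable += 1
                    conc += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
        assert concordance_index(risk, times, events) == pytest.approx(conc / usable)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index as li_ci
        n = 60
        times = rng.exponential(5, n) + np.linspace(0, 1e-4, n)  # no exact ties
        events = (rng.random(n) < 0.7).astype(int)
        risk = rng.normal(size=n)
        want = li_ci(times, -risk, events)  # lifelines expects survival scores
        assert concordance_index(risk, times, events) == pytest.approx(want, rel=1e-9)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [3.0, 3.0], [0, 0])
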