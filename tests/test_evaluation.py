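"""Metrics, exact rank-sum, Fisher/chi-square, cohort and rater tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from euscv.evaluation import (
    aggregate_folds,
    auroc,
    categorical_p,
    chi2_p,
    cohort_table,
    compare_fold_scores,
    confusion_metrics,
    exact_rank_sum_p,
    fisher_exact_p,
    rater_summary,
)


def pairwise_auroc_oracle(scores, labels) -> float:
    """Exhaustive positive-negative pair comparison with tie half-credit."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def hypergeom_fisher_oracle(table) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    def pmf(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in support if pmf(x) <= p_obs * (1 + 1e-9))


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_half_of_pairs_correct(self):
        # 2 of the 4 positive>negative pairs are correctly ordered
        assert auroc([0.8, 0.3, 0.6, 0.5], [1, 1, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_pairwise_oracle_and_sklearn(self, data):
        n = data.draw(st.integers(4, 50))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        )
        got = auroc(scores, labels)
        assert got == pytest.approx(pairwise_auroc_oracle(scores, labels), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        base = auroc(scores, labels)
        assert auroc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert auroc(2 * scores - 5, labels) == pytest.approx(base)


class TestConfusionMetrics:
    def test_direct_counting_example(self):
        m = confusion_metrics([0.9, 0.4, 0.7, 0.2], [1, 1, 0, 0])
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(m, name) == 0.5

    def test_perfect_scores(self):
        m = confusion_metrics([0.99, 0.95, 0.1, 0.05], [1, 1, 0, 0])
        assert all(getattr(m, k) == 1.0 for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auroc"))

    def test_cohort_scale_counting(self):
        """61 positives / 24 negatives with TP=41, TN=12 gives accuracy
        53/85, the scale of a per-patient human-reader row."""
        labels = [1] * 61 + [0] * 24
        scores = [1.0] * 41 + [0.0] * 20 + [0.0] * 12 + [1.0] * 12
        m = confusion_metrics(scores, labels)
        assert (m.tp, m.fn, m.tn, m.fp) == (41, 20, 12, 12)
        assert m.accuracy == pytest.approx(53 / 85)

    def test_threshold_boundary_counts_positive(self):
        m = confusion_metrics([0.5], [1])
        assert m.tp == 1

    def test_undefined_ppv_is_nan(self):
        m = confusion_metrics([0.1, 0.2], [1, 0])
        assert np.isnan(m.ppv) and m.tp == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_metric_identities(self, data):
        n = data.draw(st.integers(2, 40))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n))
        m = confusion_metrics(scores, labels)
        assert m.tp + m.fn == m.n_positive == sum(labels)
        assert m.tn + m.fp == m.n_negative == n - sum(labels)
        assert m.accuracy == pytest.approx(
            (m.sensitivity * m.n_positive + m.specificity * m.n_negative) / n
        )


class TestAggregateFolds:
    def _metrics(self, **kw):
        base = dict(auroc=0.8, accuracy=0.8, sensitivity=0.8, specificity=0.8,
                    ppv=0.8, npv=0.8, tp=1, fp=1, tn=1, fn=1, threshold=0.5,
                    n_positive=2, n_negative=2)
        base.update(kw)
        from euscv.evaluation import BinaryMetrics

        return BinaryMetrics(**base)

    def test_identical_sets_preserved(self):
        agg = aggregate_folds([self._metrics()] * 5)
        assert agg["mean"]["auroc"] == pytest.approx(0.8)

    def test_arithmetic_mean(self):
        folds = [self._metrics(auroc=v) for v in (0.6, 0.7, 0.8, 0.9, 1.0)]
        assert aggregate_folds(folds)["mean"]["auroc"] == pytest.approx(0.8)

    def test_undefined_entries_excluded_and_flagged(self):
        folds = [self._metrics(npv=float("nan"))] + [self._metrics(npv=0.6)] * 4
        agg = aggregate_folds(folds)
        assert agg["mean"]["npv"] == pytest.approx(0.6)
        assert agg["n_defined"]["npv"] == 4

    def test_wrong_fold_count_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([self._metrics()] * 4)


class TestExactRankSum:
    def test_identical_samples_give_one(self):
        assert exact_rank_sum_p([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)

    def test_fully_separated_five_vs_five(self):
        a = [0.9, 0.91, 0.92, 0.93, 0.94]
        b = [0.1, 0.11, 0.12, 0.13, 0.14]
        assert exact_rank_sum_p(a, b) == pytest.approx(2 / 252)

    def test_symmetry(self, rng):
        a, b = rng.random(5), rng.random(5)
        assert exact_rank_sum_p(a, b) == pytest.approx(exact_rank_sum_p(b, a))

    def test_matches_scipy_exact_on_tie_free_samples(self, rng):
        for _ in range(10):
            a, b = rng.random(5), rng.random(5)
            ours = exact_rank_sum_p(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_fold_scores([1, 2, 3], [1, 2])


class TestCategoricalTests:
    def test_proportionally_identical_table_gives_one(self):
        assert fisher_exact_p([[10, 10], [5, 5]]) == pytest.approx(1.0)
        assert categorical_p(10, 20, 5, 10) == pytest.approx(1.0)

    def test_transposition_invariance(self, rng):
        for _ in range(10):
            t = rng.integers(1, 30, size=(2, 2))
            assert fisher_exact_p(t) == pytest.approx(fisher_exact_p(t.T), abs=1e-12)

    def test_matches_hypergeometric_enumeration_oracle(self, rng):
        for _ in range(15):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            assert fisher_exact_p(t) == pytest.approx(hypergeom_fisher_oracle(t), rel=1e-9)

    def test_chi2_without_correction(self):
        # hand value: Pearson X2 on [[10,10],[2,18]] = 7.619, df 1
        x2 = 40 * (10 * 18 - 10 * 2) ** 2 / (20 * 20 * 12 * 28)
        assert chi2_p([[10, 10], [2, 18]]) == pytest.approx(stats.chi2.sf(x2, 1))


class TestTables:
    def _metadata(self):
        rng = np.random.default_rng(0)
        n = 60
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "label": [1] * 40 + [0] * 20,
                "age_years": rng.normal(70, 8, n).round(1),
                "bmi": rng.normal(22, 2, n).round(1),
                "alcohol_g_per_day": rng.gamma(2, 10, n).round(1),
                "alcohol_category": rng.choice(["light", "moderate", "heavy"], n, p=[0.6, 0.3, 0.1]),
                "session_date": rng.integers(736000, 738000, n),
                "eda_score": rng.random(n).round(3),
            }
        )

    def test_cohort_table_structure_and_pvalues(self):
        table = cohort_table(self._metadata())
        assert {"Age, years", "Alcohol light"} <= set(table["characteristic"])
        assert table["p_value"].between(0, 1).all()

    def test_cohort_table_chi2_option(self):
        t_f = cohort_table(self._metadata(), method="fisher")
        t_c = cohort_table(self._metadata(), method="chi2")
        # continuous rows identical, categorical rows generally differ
        assert t_f.iloc[0]["p_value"] == t_c.iloc[0]["p_value"]

    def test_empty_class_rejected(self):
        meta = self._metadata()
        with pytest.raises(ValueError):
            cohort_table(meta[meta["label"] == 1])

    def test_rater_summary_degenerate_panels(self):
        labels = {"a": 1, "b": 1, "c": 0, "d": 0}
        diagnoses = pd.DataFrame(
            [[1, 1, 0, 0], [1, 0, 1, 0]],
            index=["expert_0", "novice_0"],
            columns=list(labels),
        )
        summary = rater_summary(diagnoses, labels, ["expert_0"], ["novice_0"])
        assert summary.loc["experts", "accuracy"] == 1.0
        assert summary.loc["novices", "accuracy"] == 0.5
        assert summary.loc["all", "accuracy"] == 0.75
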