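"""Binary-classification metrics, fold aggregation and cohort statistics.

Conventions follow the study design: label 0 = AIP (negative class),
label 1 = PDAC (positive class); the decision threshold is 0.5 with a
score exactly at the threshold counted as positive.  AUROC is the
rank-based (Mann-Whitney) estimator with half-credit for ties, which
equals the trapezoidal area under the empirical ROC curve.

Ordered-vs-balanced comparisons of the five per-fold metric values use an
*exact* two-sided Wilcoxon rank-sum test: with 5 values per side all
C(10, 5) = 252 assignments of ranks are enumerated, with mid-ranks under
ties.  Cohort characteristics tables report median (range) with the
Wilcoxon rank-sum test for continuous covariates, and counts (%) with a
two-sided test on the 2x2 category-vs-rest table for categorical ones
(Fisher's exact by default; Pearson chi-square without continuity
correction available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "BinaryMetrics",
    "auroc",
    "confusion_metrics",
    "aggregate_folds",
    "compare_fold_scores",
    "exact_rank_sum_p",
    "fisher_exact_p",
    "chi2_p",
    "categorical_p",
    "cohort_table",
    "rater_summary",
]

METRIC_NAMES = ("auroc", "accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class BinaryMetrics:
    """Threshold metrics plus AUROC for one score/label set.

    ``ppv``/``npv`` are NaN when the corresponding predicted class is
    empty (undefined rather than zero).
    """

    auroc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    n_positive: int
    n_negative: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def auroc(scores, labels) -> float:
    """Rank-based AUROC (Mann-Whitney with half-credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)  # mid-ranks under ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> BinaryMetrics:
    """Confusion-matrix metrics at a threshold (score >= threshold -> 1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0 (AIP) or 1 (PDAC)")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    total = n_pos + n_neg
    try:
        auc = auroc(scores, labels)
    except ValueError:
        auc = float("nan")
    return BinaryMetrics(
        auroc=auc,
        accuracy=(tp + tn) / total if total else float("nan"),
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
        ppv=tp / (tp + fp) if (tp + fp) else float("nan"),
        npv=tn / (tn + fn) if (tn + fn) else float("nan"),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        threshold=threshold,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def aggregate_folds(folds: Sequence[BinaryMetrics]) -> dict[str, object]:
    """Unweighted mean of each metric over exactly five folds.

    NaN (undefined) entries are excluded from the mean; the returned
    ``n_defined`` mapping flags how many folds contributed to each metric.
    """
    if len(folds) != 5:
        raise ValueError(f"expected exactly 5 fold metrics, got {len(folds)}")
    means: dict[str, float] = {}
    n_defined: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        ok = ~np.isnan(vals)
        n_defined[name] = int(ok.sum())
        means[name] = float(vals[ok].mean()) if ok.any() else float("nan")
    return {"mean": means, "n_defined": n_defined}


def exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value by full enumeration.

    Mid-ranks are assigned to the pooled sample; the null distribution of
    the group-A rank sum is built by enumerating all C(n_a + n_b, n_a)
    assignments of the (possibly tied) ranks.  Two-sided p = probability
    of a rank sum at least as far from its null mean as observed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("the two sides must have equal lengths")
    if len(a) == 0:
        raise ValueError("empty samples")
    n = len(a) + len(b)
    if math.comb(n, len(a)) > 500_000:
        raise ValueError("sample too large for exact enumeration")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    observed = ranks[: len(a)].sum()
    mean = len(a) * (n + 1) / 2.0
    dev = abs(observed - mean)
    count = 0
    total = 0
    for comb in combinations(range(n), len(a)):
        total += 1
        if abs(ranks[list(comb)].sum() - mean) >= dev - 1e-12:
            count += 1
    return count / total


def compare_fold_scores(mode_a: Sequence[float], mode_b: Sequence[float]) -> float:
    """Two-sided exact rank-sum p comparing the 5 per-fold values of one
    metric between the ordered and balanced divisions of a factor."""
    return exact_rank_sum_p(mode_a, mode_b)


def fisher_exact_p(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p on a 2x2 table (sum of hypergeometric
    probabilities <= the observed table's probability)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def chi2_p(table: Sequence[Sequence[int]]) -> float:
    """Pearson chi-square p on a 2x2 table, without continuity correction."""
    return float(stats.chi2_contingency(np.asarray(table), correction=False)[1])


def categorical_p(
    n1_in: int, n1_total: int, n0_in: int, n0_total: int, method: str = "fisher"
) -> float:
    """Two-sided association p for a category-vs-rest 2x2 split between
    the two classes; ``method`` is 'fisher' or 'chi2'."""
    table = [[n1_in, n1_total - n1_in], [n0_in, n0_total - n0_in]]
    if method == "fisher":
        return fisher_exact_p(table)
    if method == "chi2":
        return chi2_p(table)
    raise ValueError(f"unknown method {method!r}")


_CONTINUOUS = [("age_years", "Age, years"), ("bmi", "BMI, kg/m2"),
               ("alcohol_g_per_day", "Alcohol, g/day")]
_CATEGORICAL_LEVELS = ["light", "moderate", "heavy"]


def cohort_table(metadata: pd.DataFrame, method: str = "fisher") -> pd.DataFrame:
    """Cohort-characteristics summary by class.

    Continuous covariates: median (range) per class + two-sided Wilcoxon
    rank-sum p.  Alcohol categories: n (%) per class + two-sided
    category-vs-rest p (``method``: 'fisher' or 'chi2').
    """
    pos = metadata[metadata["label"] == 1]
    neg = metadata[metadata["label"] == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present in the metadata")
    rows = []
    for col, name in _CONTINUOUS:
        if col not in metadata.columns:
            continue
        x, y = pos[col].to_numpy(float), neg[col].to_numpy(float)
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append(
            {
                "characteristic": name,
                "pdac": f"{np.median(x):g} ({x.min():g}-{x.max():g})",
                "aip": f"{np.median(y):g} ({y.min():g}-{y.max():g})",
                "p_value": p,
            }
        )
    if "alcohol_category" in metadata.columns:
        for level in _CATEGORICAL_LEVELS:
            n1 = int((pos["alcohol_category"] == level).sum())
            n0 = int((neg["alcohol_category"] == level).sum())
            p = categorical_p(n1, len(pos), n0, len(neg), method=method)
            rows.append(
                {
                    "characteristic": f"Alcohol {level}",
                    "pdac": f"{n1} ({100 * n1 / len(pos):.1f})",
                    "aip": f"{n0} ({100 * n0 / len(neg):.1f})",
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def rater_summary(
    diagnoses: pd.DataFrame,
    labels: Mapping[str, int],
    expert_ids: Sequence[str],
    novice_ids: Sequence[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Mean per-rater metrics for the 'all' / 'experts' / 'novices' panels.

    ``diagnoses`` is raters x patients with binary calls; each rater's
    confusion metrics are computed against the patient labels and averaged
    within the panel (AUROC is omitted: binary calls carry no ranking).
    """
    y = np.array([labels[pid] for pid in diagnoses.columns])
    per_rater = {}
    for rid in diagnoses.index:
        m = confusion_metrics(diagnoses.loc[rid].to_numpy(float), y, threshold)
        per_rater[rid] = {k: v for k, v in m.as_dict().items() if k != "auroc"}
    table = pd.DataFrame(per_rater).T
    groups = {
        "all": list(diagnoses.index),
        "experts": list(expert_ids),
        "novices": list(novice_ids),
    }
    return pd.DataFrame({g: table.loc[ids].mean() for g, ids in groups.items() if ids}).T
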