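"""Imbalance-aware classification metrics and distribution comparisons."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_auc",
    "compute_metrics",
    "compare_metric_distributions",
    "holm_adjust",
]

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "gmean", "ppv", "npv")


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank (Mann-Whitney) statistic with ties counted 1/2."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(
    predicted_classes: np.ndarray, scores: np.ndarray | None, labels: np.ndarray
) -> dict[str, float]:
    """Confusion-matrix metrics plus rank AUC.

    Metrics undefined on the given label mix (e.g. sensitivity without
    positives) are reported as NaN with a warning rather than coerced to 0,
    so aggregated means and SDs stay honest.
    """
    y = np.asarray(labels)
    c = np.asarray(predicted_classes)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    tp = int(((c == 1) & (y == 1)).sum())
    tn = int(((c == 0) & (y == 0)).sum())
    fp = int(((c == 1) & (y == 0)).sum())
    fn = int(((c == 0) & (y == 1)).sum())

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator); reported as NaN")
            return float("nan")
        return num / den

    sens = _ratio(tp, n_pos, "sensitivity")
    spec = _ratio(tn, n_neg, "specificity")
    out = {
        "auc": rank_auc(scores, y) if scores is not None else float("nan"),
        "accuracy": (tp + tn) / len(y),
        "sensitivity": sens,
        "specificity": spec,
        "gmean": float(np.sqrt(sens * spec)),
        "ppv": _ratio(tp, tp + fp, "PPV"),
        "npv": _ratio(tn, tn + fn, "NPV"),
    }
    return out


def compare_metric_distributions(
    dist_a: np.ndarray, dist_b: np.ndarray, paired: bool = False
) -> float:
    """Two-sided p-value comparing two metric distributions.

    Paired samples (matched repetition schedules) use the Wilcoxon
    signed-rank test; independent samples use the Wilcoxon rank-sum
    (Mann-Whitney U) test, exact where sample sizes permit.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison needs matched repetition schedules")
        diffs = a - b
        if np.all(diffs == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 1.0
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Bonferroni-Holm step-down adjustment for multiple comparisons."""
    _, adjusted, _, _ = multipletests(p_values, method="holm")
    return [float(p) for p in adjusted]
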