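"""Feature-table hygiene: redundancy filtering, robustness filtering and
train-only standardization.

The redundancy filter is supervised (it ranks correlated features by their
univariate discrimination of the response), so in the nested cross-validation
it must only ever see inner-training rows; the API therefore operates on a
training partition passed in explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .tables import FeatureTable

__all__ = [
    "univariate_auc",
    "redundancy_filter",
    "robustness_filter",
    "icc_agreement",
    "StandardizationParams",
    "zscore_fit",
    "zscore_apply",
]


def univariate_auc(feature_values: np.ndarray, labels: np.ndarray) -> float:
    """AUC of a univariate logistic model on one feature.

    By monotonicity of the logistic link this equals the rank AUC of the raw
    feature, orientation-corrected (``max(a, 1-a)``) because the fitted slope
    takes whichever sign discriminates.
    """
    y = np.asarray(labels)
    x = np.asarray(feature_values, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    a = float(roc_auc_score(y, x))
    return max(a, 1.0 - a)


def _spearman_abs(X: pd.DataFrame) -> np.ndarray:
    ranks = np.apply_along_axis(stats.rankdata, 0, X.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.nan_to_num(rho, nan=0.0)  # constant columns correlate with nothing
    return np.abs(rho)


def redundancy_filter(
    table: pd.DataFrame | FeatureTable,
    labels: np.ndarray | None = None,
    rho_threshold: float = 0.90,
) -> list[str]:
    """Collapse blocks of rank-correlated features, keeping the most predictive.

    While any pair of surviving features has Spearman ``|rho| >=
    rho_threshold``, the strongest such pair is taken (ties broken by
    lexicographic feature-name order) and its member with the lower
    univariate AUC is dropped (AUC ties drop the alphabetically later name).
    Supervised: call on (inner-)training rows only. Returns survivors in
    original column order.
    """
    if isinstance(table, FeatureTable):
        X, y = table.features, table.labels.to_numpy()
    else:
        X, y = table, np.asarray(labels)
    names = list(X.columns)
    n_feat = len(names)
    rho = _spearman_abs(X)
    np.fill_diagonal(rho, 0.0)
    aucs = np.array([univariate_auc(X[name].to_numpy(), y) for name in names])

    alive = np.ones(n_feat, dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], rho, 0.0)
        top = sub.max()
        if top < rho_threshold:
            break
        cand = np.argwhere(np.triu(sub, 1) == top)
        # strongest pair first; exact ties resolved by lexicographic name order
        i, j = min(cand, key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))))
        a, b = names[i], names[j]
        if aucs[i] > aucs[j]:
            drop = j
        elif aucs[j] > aucs[i]:
            drop = i
        else:
            drop = i if a > b else j  # AUC tie: drop the later name alphabetically
        alive[drop] = False
    return [names[k] for k in range(n_feat) if alive[k]]


def icc_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, single-measurement ICC.

    ICC(2,1) of an n-subjects x 2-measurements layout, as produced by
    feature extraction on original vs perturbed segmentations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two aligned 1D measurement vectors")
    import pingouin  # deferred: heavy import, only needed for this optional filter

    n = x.size
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["orig", "perturbed"], n),
            "value": np.concatenate([x, y]),
        }
    )
    res = pingouin.intraclass_corr(
        long, targets="subject", raters="rater", ratings="value"
    )
    # two-way random effects, absolute agreement, single measurement
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    val = float(res.loc[sel, "ICC"].iloc[0])
    return val if np.isfinite(val) else 0.0


def robustness_filter(
    table_original: pd.DataFrame,
    table_perturbed: pd.DataFrame,
    icc_threshold: float = 0.75,
) -> list[str]:
    """Retain features that agree between original and perturbed segmentations.

    ``table_perturbed`` holds the same patients' features extracted from
    masks perturbed by one-voxel morphological erosion/dilation; features
    with two-way agreement ICC below the threshold are considered unstable
    and dropped.
    """
    if list(table_original.index) != list(table_perturbed.index):
        raise ValueError("original and perturbed tables must cover identical patients")
    common = [c for c in table_original.columns if c in table_perturbed.columns]
    kept = []
    for name in common:
        a = table_original[name].to_numpy(dtype=float)
        b = table_perturbed[name].to_numpy(dtype=float)
        if np.allclose(a, b):
            kept.append(name)  # identical measurements are perfectly robust
            continue
        if icc_agreement(a, b) >= icc_threshold:
            kept.append(name)
    return kept


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and sample (n-1) standard deviation from training rows."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    stds: np.ndarray


def zscore_fit(train: pd.DataFrame) -> StandardizationParams:
    """Fit z-score parameters on training rows; constant features are removed."""
    means = train.mean(axis=0)
    stds = train.std(axis=0, ddof=1)
    keep = stds > 0
    if not keep.all():
        dropped = list(stds.index[~keep])
        warnings.warn(f"removing constant features before standardization: {dropped}")
    names = tuple(stds.index[keep])
    return StandardizationParams(
        names,
        means[list(names)].to_numpy(dtype=float),
        stds[list(names)].to_numpy(dtype=float),
    )


def zscore_apply(matrix: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Standardize rows (training or test) with training parameters."""
    X = matrix[list(params.feature_names)].to_numpy(dtype=float)
    return pd.DataFrame(
        (X - params.means) / params.stds,
        index=matrix.index,
        columns=params.feature_names,
    )
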