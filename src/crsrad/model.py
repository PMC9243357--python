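"""Elastic Net logistic modeling in nested stratified cross-validation.

The design follows the study setup: an outer k-fold loop (default 5) gives
unbiased test predictions while an inner k-fold loop (default 5), run on
each outer-training partition, performs every data-dependent decision --
supervised redundancy filtering, z-score standardization, shrinkage
selection by minimum mean validation deviance, and decision-threshold
optimization by G-mean. The whole procedure is repeated (default 100 times)
on random permutations of the cohort, yielding k_outer x n_repetitions
fitted model instances (500 at the defaults).

The penalized objective is

    mean logistic deviance + lambda * (alpha*||b||_1 + (1-alpha)*||b||_2^2/2)

with an unpenalized intercept; alpha (the L1/L2 mixing) defaults to 0.5 and
only lambda is tuned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from ._seeds import derive_seed
from .metrics import compute_metrics
from .preprocessing import StandardizationParams, redundancy_filter, zscore_apply, zscore_fit
from .tables import FeatureTable

__all__ = [
    "CVConfig",
    "ElasticNetConfig",
    "FittedModel",
    "NestedCVResult",
    "RepetitionResults",
    "fit_elastic_net",
    "lambda_grid",
    "select_lambda",
    "optimize_threshold",
    "nested_cv_run",
    "repeat_nested_cv",
]


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation layout."""

    k_outer: int = 5
    k_inner: int = 5
    n_repetitions: int = 100
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("nested CV needs at least 2 folds per loop")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")


@dataclass(frozen=True)
class ElasticNetConfig:
    """Elastic Net settings: L1/L2 mixing and the lambda path."""

    alpha: float = 0.5
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-2
    tol: float = 1e-4
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_lambda < 50:
            raise ValueError("lambda grid must have at least 50 points")


@dataclass
class FittedModel:
    """One deployed model: retained features, scaling, coefficients, threshold."""

    feature_names: tuple[str, ...]
    standardization: StandardizationParams
    beta: np.ndarray
    intercept: float
    lam: float
    tau: float

    def coefficient_map(self) -> dict[str, float]:
        return {n: float(b) for n, b in zip(self.standardization.feature_names, self.beta)}

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.standardization.feature_names if n not in features.columns]
        if missing:
            raise KeyError(f"feature table is missing required features: {missing}")
        Z = zscore_apply(features, self.standardization).to_numpy()
        logits = Z @ self.beta + self.intercept
        return 1.0 / (1.0 + np.exp(-logits))

    def predict_class(self, features: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(features) >= self.tau).astype(int)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "standardized_features": list(self.standardization.feature_names),
            "means": self.standardization.means.tolist(),
            "stds": self.standardization.stds.tolist(),
            "beta": np.asarray(self.beta).tolist(),
            "intercept": float(self.intercept),
            "lambda": float(self.lam),
            "tau": float(self.tau),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        params = StandardizationParams(
            tuple(d["standardized_features"]),
            np.asarray(d["means"], dtype=float),
            np.asarray(d["stds"], dtype=float),
        )
        return cls(
            tuple(d["feature_names"]),
            params,
            np.asarray(d["beta"], dtype=float),
            float(d["intercept"]),
            float(d["lambda"]),
            float(d["tau"]),
        )


def _make_estimator(lam: float, alpha: float, n: int, tol: float, max_iter: int):
    return LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=1.0 / (n * lam),
        tol=tol,
        max_iter=max_iter,
        warm_start=True,
        random_state=0,  # saga shuffles; fix it so runs are bit-reproducible
    )


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> tuple[np.ndarray, float]:
    """Fit one penalized logistic regression; returns (beta, intercept).

    ``X`` is expected standardized; the intercept is unpenalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    est = _make_estimator(lam, alpha, len(y), tol, max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"elastic net did not converge (lambda={lam:.3g}, alpha={alpha}, "
                f"n={len(y)}, max_iter={max_iter}): {exc}"
            ) from exc
    beta = est.coef_.ravel().copy()
    b0 = float(est.intercept_[0])
    if np.all(beta == 0.0):
        b0 = _null_intercept(y)
    return beta, b0


def _null_intercept(y: np.ndarray) -> float:
    """Exact unpenalized intercept of the null model: logit of the prevalence.

    The solver's stopping rule can quit early when every coefficient is
    shrunk to zero; the restricted optimum is available in closed form.
    """
    p = float(np.mean(y))
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1.0 - p)))


def lambda_grid(X: np.ndarray, y: np.ndarray, config: ElasticNetConfig) -> np.ndarray:
    """Descending log-spaced lambda path.

    The top of the path is the smallest lambda that zeroes every coefficient
    under the L1 part (for alpha > 0); for pure ridge the same scale anchors
    an arbitrary but data-adapted grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    resid = y - y.mean()
    score = np.abs(X.T @ resid) / n
    alpha_eff = max(config.alpha, 1e-3)
    lam_max = max(float(score.max()) / alpha_eff, 1e-6) * 1.001
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def _deviance(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def _path_fit(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    lambdas: np.ndarray,
    config: ElasticNetConfig,
) -> list[tuple[np.ndarray, float]]:
    """Fit the full descending lambda path with warm starts."""
    est = _make_estimator(lambdas[0], config.alpha, len(y_tr), config.tol, config.max_iter)
    out = []
    with warnings.catch_warnings():
        # deep-path fits may stop at max_iter; fine for model selection
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            est.C = 1.0 / (len(y_tr) * lam)
            est.fit(X_tr, y_tr)
            beta = est.coef_.ravel().copy()
            b0 = float(est.intercept_[0])
            if np.all(beta == 0.0):
                b0 = _null_intercept(y_tr)
            out.append((beta, b0))
    return out


def optimize_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing the G-mean of the thresholded classifier.

    Candidates are the midpoints of sorted unique scores; among maximizers
    the smallest threshold is returned. Degenerate all-equal scores return
    0.5 (any threshold yields the same prediction set).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to optimize the threshold")
    uniq = np.unique(s)
    if uniq.size < 2:
        return 0.5
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = float((y == 1).sum())
    n_neg = float((y == 0).sum())
    # predicted positive iff score >= tau
    pred = s[None, :] >= cands[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    tn = (~pred & (y == 0)).sum(axis=1)
    gmean = np.sqrt((tp / n_pos) * (tn / n_neg))
    best = gmean.max()
    return float(cands[np.flatnonzero(gmean == best)[0]])


def _fold_splitter(k: int, stratified: bool, seed: int):
    if stratified:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return KFold(n_splits=k, shuffle=True, random_state=seed)


def _inner_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    cv_config: CVConfig,
    enet_config: ElasticNetConfig,
    seed: int,
    skip_redundancy: bool,
    rho_threshold: float,
):
    """Inner loop: per-fold filtering + standardization, lambda path, pooled
    validation scores. Returns (lambda_star, pooled_scores, pooled_labels)."""
    lambdas = lambda_grid(
        (features - features.mean()) / features.std(ddof=1).replace(0.0, 1.0),
        labels,
        enet_config,
    )
    splitter = _fold_splitter(cv_config.k_inner, cv_config.stratified, seed)
    try:
        folds = list(splitter.split(features, labels))
    except ValueError as exc:
        raise ValueError(f"inner stratification failed: {exc}") from exc

    dev = np.zeros((len(folds), len(lambdas)))
    val_probs: list[np.ndarray] = []
    val_labels: list[np.ndarray] = []
    for f, (tr, va) in enumerate(folds):
        X_tr_df = features.iloc[tr]
        y_tr = labels[tr]
        if skip_redundancy:
            retained = list(features.columns)
        else:
            retained = redundancy_filter(X_tr_df, y_tr, rho_threshold)
        params = zscore_fit(X_tr_df[retained])
        Z_tr = zscore_apply(X_tr_df, params).to_numpy()
        Z_va = zscore_apply(features.iloc[va], params).to_numpy()
        y_va = labels[va]
        path = _path_fit(Z_tr, y_tr, lambdas, enet_config)
        probs_per_lam = []
        for beta, b0 in path:
            p = 1.0 / (1.0 + np.exp(-(Z_va @ beta + b0)))
            probs_per_lam.append(p)
        dev[f] = [_deviance(p, y_va) for p in probs_per_lam]
        val_probs.append(np.stack(probs_per_lam))
        val_labels.append(y_va)

    mean_dev = dev.mean(axis=0)
    best_idx = int(np.argmin(mean_dev))  # grid descends, so ties go to larger lambda
    lam_star = float(lambdas[best_idx])
    pooled_scores = np.concatenate([vp[best_idx] for vp in val_probs])
    pooled_labels = np.concatenate(val_labels)
    return lam_star, pooled_scores, pooled_labels


def select_lambda(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    enet_config: ElasticNetConfig | None = None,
    cv_config: CVConfig | None = None,
    seed: int = 0,
) -> float:
    """Choose the shrinkage parameter by inner k-fold CV on training data.

    Minimizes the mean validation deviance over a descending lambda grid;
    ties resolve to the larger (more parsimonious) lambda.
    """
    enet_config = enet_config or ElasticNetConfig()
    cv_config = cv_config or CVConfig()
    lam, _, _ = _inner_select(
        X_train,
        np.asarray(y_train),
        cv_config,
        enet_config,
        seed,
        skip_redundancy=True,
        rho_threshold=0.90,
    )
    return lam


@dataclass
class NestedCVResult:
    """One nested-CV pass: k_outer fitted models and pooled outer predictions."""

    models: list[FittedModel]
    fold_train_rows: list[np.ndarray]
    fold_test_rows: list[np.ndarray]
    outer_scores: np.ndarray
    outer_classes: np.ndarray
    outer_labels: np.ndarray

    def metrics(self) -> dict[str, float]:
        return compute_metrics(self.outer_classes, self.outer_scores, self.outer_labels)


def nested_cv_run(
    table: FeatureTable,
    cv_config: CVConfig | None = None,
    enet_config: ElasticNetConfig | None = None,
    permutation_seed: int = 0,
    skip_redundancy: bool = False,
    rho_threshold: float = 0.90,
) -> NestedCVResult:
    """One nested cross-validation pass over a random permutation of the cohort.

    Every supervised decision (redundancy filtering, standardization, lambda,
    threshold) is made inside the outer-training partition; outer-test rows
    are scored exactly once and touch nothing else.
    """
    cv_config = cv_config or CVConfig()
    enet_config = enet_config or ElasticNetConfig()
    features, labels = table.features, table.labels.to_numpy()

    splitter = _fold_splitter(cv_config.k_outer, cv_config.stratified, permutation_seed)
    try:
        folds = list(splitter.split(features, labels))
    except ValueError as exc:
        raise ValueError(f"outer stratification failed: {exc}") from exc

    models: list[FittedModel] = []
    train_rows, test_rows = [], []
    scores = np.full(len(labels), np.nan)
    classes = np.full(len(labels), -1, dtype=int)
    for fold_id, (tr, te) in enumerate(folds):
        X_tr_df = features.iloc[tr]
        y_tr = labels[tr]
        lam_star, inner_scores, inner_labels = _inner_select(
            X_tr_df,
            y_tr,
            cv_config,
            enet_config,
            derive_seed(permutation_seed, "inner", fold_id),
            skip_redundancy,
            rho_threshold,
        )
        tau = optimize_threshold(inner_scores, inner_labels)

        if skip_redundancy:
            retained = list(features.columns)
        else:
            retained = redundancy_filter(X_tr_df, y_tr, rho_threshold)
        params = zscore_fit(X_tr_df[retained])
        Z_tr = zscore_apply(X_tr_df, params).to_numpy()
        beta, b0 = fit_elastic_net(
            Z_tr, y_tr, lam_star, enet_config.alpha, enet_config.tol, enet_config.max_iter
        )
        model = FittedModel(tuple(retained), params, beta, b0, lam_star, tau)
        models.append(model)
        train_rows.append(tr)
        test_rows.append(te)

        p_te = model.predict_proba(features.iloc[te])
        scores[te] = p_te
        classes[te] = (p_te >= tau).astype(int)

    return NestedCVResult(models, train_rows, test_rows, scores, classes, labels.copy())


@dataclass
class RepetitionResults:
    """All model instances and per-repetition pooled outer-fold metrics."""

    runs: list[NestedCVResult]
    metrics: pd.DataFrame
    feature_names: tuple[str, ...]

    @property
    def models(self) -> list[FittedModel]:
        return [m for run in self.runs for m in run.models]

    @property
    def n_instances(self) -> int:
        return len(self.models)


def repeat_nested_cv(
    table: FeatureTable,
    cv_config: CVConfig | None = None,
    enet_config: ElasticNetConfig | None = None,
    skip_redundancy: bool = False,
    rho_threshold: float = 0.90,
) -> RepetitionResults:
    """Repeat nested CV on fresh random permutations of the cohort.

    At the defaults (5 outer folds x 100 repetitions) this yields the 500
    fitted model instances over which the occurrence analysis and
    coefficient averaging run.
    """
    cv_config = cv_config or CVConfig()
    enet_config = enet_config or ElasticNetConfig()
    runs = []
    rows = []
    for rep in range(cv_config.n_repetitions):
        run = nested_cv_run(
            table,
            cv_config,
            enet_config,
            permutation_seed=derive_seed(cv_config.base_seed, "rep", rep),
            skip_redundancy=skip_redundancy,
            rho_threshold=rho_threshold,
        )
        runs.append(run)
        rows.append(run.metrics())
    metrics = pd.DataFrame(rows)
    metrics.index.name = "repetition"
    return RepetitionResults(runs, metrics, tuple(table.feature_names))
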