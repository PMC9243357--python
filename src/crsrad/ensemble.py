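"""Majority-voting ensemble for external testing, plus the volumetric baseline.

The deployed predictor for an external cohort is the ensemble of the
k_outer (default 5, odd so votes cannot tie) cross-validated Elastic Net
models from one nested-CV pass over the discovery cohort: each member
standardizes the external features with its own training parameters, scores
them, thresholds at its own optimized decision threshold and votes; the
predicted class is the majority vote. The continuous ensemble score used for
AUC is the mean member probability (vote fraction is available as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import compare_metric_distributions, compute_metrics, holm_adjust, rank_auc
from .model import (
    CVConfig,
    ElasticNetConfig,
    FittedModel,
    NestedCVResult,
    RepetitionResults,
    repeat_nested_cv,
)
from .tables import FeatureTable

__all__ = [
    "EnsembleModel",
    "majority_vote",
    "ensemble_predict",
    "volumetric_baseline",
    "compute_metrics",
    "compare_metric_distributions",
    "holm_adjust",
]


def majority_vote(votes: np.ndarray | list[int]) -> int:
    """Majority class of an odd number of binary votes."""
    v = np.asarray(votes)
    if v.size % 2 == 0:
        raise ValueError("vote count must be odd so the majority is defined")
    if not np.all(np.isin(v, (0, 1))):
        raise ValueError("votes must be binary")
    return int(v.sum() * 2 > v.size)


@dataclass
class EnsembleModel:
    """A fixed set of fitted models combined by majority voting."""

    members: list[FittedModel]

    def __post_init__(self) -> None:
        if len(self.members) % 2 == 0:
            raise ValueError("ensemble size must be odd so votes cannot tie")

    @classmethod
    def from_run(cls, run: NestedCVResult) -> "EnsembleModel":
        return cls(list(run.models))

    def predict(self, features: pd.DataFrame, score: str = "mean_probability"):
        """Per-patient majority class and continuous ensemble score.

        Returns ``(classes, scores)``; the class depends only on member
        votes, never on the averaged probabilities.
        """
        probs = np.stack([m.predict_proba(features) for m in self.members])
        votes = np.stack(
            [(p >= m.tau).astype(int) for p, m in zip(probs, self.members)]
        )
        classes = (votes.sum(axis=0) * 2 > len(self.members)).astype(int)
        if score == "mean_probability":
            scores = probs.mean(axis=0)
        elif score == "vote_fraction":
            scores = votes.mean(axis=0)
        else:
            raise ValueError(f"unknown ensemble score rule: {score}")
        return classes, scores


def ensemble_predict(
    ensemble: EnsembleModel, external_table: FeatureTable, score: str = "mean_probability"
) -> pd.DataFrame:
    """Score an external cohort; returns per-patient votes, score and class."""
    classes, scores = ensemble.predict(external_table.features, score=score)
    return pd.DataFrame(
        {
            "predicted_class": classes,
            "ensemble_score": scores,
            "label": external_table.labels.to_numpy(),
        },
        index=external_table.features.index,
    )


def volumetric_baseline(
    volumes: pd.Series,
    labels: pd.Series,
    cv_config: CVConfig | None = None,
    enet_config: ElasticNetConfig | None = None,
) -> RepetitionResults:
    """Single-feature (tumor volume) logistic model through the same machinery.

    Runs the identical nested CV + threshold optimization + repetition
    scheme on a one-column table, giving the volume-only reference the
    radiomics models are compared against.
    """
    if (volumes <= 0).any():
        raise ValueError("volumes must be positive")
    table = FeatureTable(volumes.to_frame(), labels)
    return repeat_nested_cv(table, cv_config, enet_config, skip_redundancy=True)
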