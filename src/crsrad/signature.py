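"""Occurrence-count stability analysis and the reduced interpretable model.

Across all fitted model instances (500 at the defaults), each feature's
occurrences -- instances in which its coefficient is non-zero -- are
counted. Features occurring in strictly more than a fraction (default 0.6,
i.e. >300 of 500) of instances form the relevant set; whole-lesion volume is
force-included for clinical recognition. The Elastic Net is then refitted on
this reduced set with identical nested-CV partitions, and coefficients are
averaged over instances for interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CVConfig, ElasticNetConfig, FittedModel, RepetitionResults, repeat_nested_cv
from .tables import FeatureTable

__all__ = [
    "SignatureReport",
    "count_occurrences",
    "select_relevant",
    "refit_reduced",
    "average_coefficients",
    "build_signature_report",
]

DEFAULT_FORCED_FEATURES = ("volume_cm3",)


def count_occurrences(
    models: list[FittedModel], feature_names: list[str] | tuple[str, ...]
) -> pd.Series:
    """Number of model instances with a non-zero coefficient per feature.

    A feature eliminated by the redundancy filter in a given instance simply
    has no coefficient there and counts as zero for that instance.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    counts = pd.Series(0, index=list(feature_names), dtype=int)
    for model in models:
        for name, beta in model.coefficient_map().items():
            if beta != 0.0 and name in counts.index:
                counts[name] += 1
    return counts


def select_relevant(
    counts: pd.Series,
    total: int,
    threshold_fraction: float = 0.6,
    forced: tuple[str, ...] = DEFAULT_FORCED_FEATURES,
) -> list[str]:
    """Features occurring in strictly more than threshold_fraction of instances.

    Forced features (by default whole-lesion volume) are appended if absent.
    Order: descending count, then name.
    """
    if total <= 0:
        raise ValueError("total instance count must be positive")
    cutoff = threshold_fraction * total
    hits = counts[counts > cutoff]
    ordered = sorted(hits.index, key=lambda n: (-int(hits[n]), n))
    for name in forced:
        if name not in ordered and name in counts.index:
            ordered.append(name)
    if not ordered:
        warnings.warn("no feature passed the occurrence threshold and none forced")
    return ordered


def refit_reduced(
    table: FeatureTable,
    selected_features: list[str],
    cv_config: CVConfig | None = None,
    enet_config: ElasticNetConfig | None = None,
) -> RepetitionResults:
    """Refit the pipeline on the curated feature subset.

    Uses the same seeds as the full run, hence identical fold partitions
    (fold assignment depends only on labels and seed); the redundancy filter
    is skipped because the set is already curated.
    """
    reduced = table.subset_features(selected_features)
    return repeat_nested_cv(reduced, cv_config, enet_config, skip_redundancy=True)


def average_coefficients(
    models: list[FittedModel],
    selected_features: list[str],
    over_all_instances: bool = True,
) -> pd.Series:
    """Mean Elastic Net coefficient per feature across model instances.

    With ``over_all_instances`` (default) an instance that does not carry
    the feature contributes 0 to the mean; otherwise the mean runs only over
    instances where the feature has a coefficient.
    """
    sums = pd.Series(0.0, index=selected_features)
    present = pd.Series(0, index=selected_features, dtype=int)
    for model in models:
        cmap = model.coefficient_map()
        for name in selected_features:
            if name in cmap:
                sums[name] += cmap[name]
                present[name] += 1
    if over_all_instances:
        return sums / len(models)
    denom = present.replace(0, 1)
    return sums / denom


@dataclass
class SignatureReport:
    """Per-feature occurrences, the selected relevant set and mean coefficients."""

    occurrence_counts: pd.Series
    total_instances: int
    selected_features: list[str]
    mean_coefficients_all: pd.Series
    mean_coefficients_present: pd.Series
    forced_features: tuple[str, ...] = DEFAULT_FORCED_FEATURES

    def to_frame(self) -> pd.DataFrame:
        """Human-readable table: feature, count, mean coefficient, sign."""
        rows = []
        for name in self.selected_features:
            coef = float(self.mean_coefficients_all[name])
            rows.append(
                {
                    "feature": name,
                    "occurrences": int(self.occurrence_counts.get(name, 0)),
                    "total_instances": self.total_instances,
                    "mean_coefficient": coef,
                    "mean_coefficient_present_only": float(
                        self.mean_coefficients_present[name]
                    ),
                    "sign": "+" if coef > 0 else ("-" if coef < 0 else "0"),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "total_instances": self.total_instances,
            "occurrence_counts": {k: int(v) for k, v in self.occurrence_counts.items()},
            "selected_features": list(self.selected_features),
            "mean_coefficients_all_instances": {
                k: float(v) for k, v in self.mean_coefficients_all.items()
            },
            "mean_coefficients_present_only": {
                k: float(v) for k, v in self.mean_coefficients_present.items()
            },
            "forced_features": list(self.forced_features),
        }


def build_signature_report(
    full_results: RepetitionResults,
    reduced_results: RepetitionResults,
    selected_features: list[str],
    forced: tuple[str, ...] = DEFAULT_FORCED_FEATURES,
) -> SignatureReport:
    """Assemble the signature report from the full and reduced runs.

    Occurrence counts come from the full run; averaged coefficients from the
    reduced refit, both averaging modes reported side by side.
    """
    counts = count_occurrences(full_results.models, full_results.feature_names)
    return SignatureReport(
        occurrence_counts=counts,
        total_instances=full_results.n_instances,
        selected_features=selected_features,
        mean_coefficients_all=average_coefficients(
            reduced_results.models, selected_features, over_all_instances=True
        ),
        mean_coefficients_present=average_coefficients(
            reduced_results.models, selected_features, over_all_instances=False
        ),
        forced_features=forced,
    )
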