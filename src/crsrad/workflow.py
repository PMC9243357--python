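"""End-to-end orchestration: simulate -> extract -> fit -> signature -> evaluate.

Each stage writes its artifacts under a run directory together with a
manifest recording the configuration hash, derived seeds and per-stage
row/feature counts, so a run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .ensemble import EnsembleModel, ensemble_predict, volumetric_baseline
from .extract import extract_cohort
from .metrics import compute_metrics
from .model import CVConfig, ElasticNetConfig, repeat_nested_cv
from .signature import build_signature_report, refit_reduced, select_relevant, count_occurrences
from .synthetic import (
    CohortSpec,
    ResponderShift,
    attach_volume_proxy,
    generate_feature_cohort,
    generate_imaging_cohort,
)
from .tables import FeatureTable

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    The default simulates the study conditions: a discovery feature cohort
    of 61 patients at 41% complete response and an external cohort of 48
    patients at 21%, with an optional small imaging cohort demonstrating
    feature extraction. Repetition count is configurable; the study default
    of 100 gives 500 model instances.
    """

    base_seed: int = 0
    out_dir: str = "results/run"
    n_discovery: int = 61
    discovery_prevalence: float = 0.41
    n_external: int = 48
    external_prevalence: float = 0.21
    n_informative: int = 5
    n_noise: int = 20
    n_redundant_per_block: int = 2
    effect_sizes: tuple[float, ...] = (1.0, 1.0, -1.0, 1.0, -1.0)
    within_block_correlation: float = 0.95
    volume_feature_scale: float = 40.0
    simulate_imaging: bool = False
    n_imaging: int = 6
    cv: CVConfig = field(default_factory=CVConfig)
    enet: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    occurrence_threshold_fraction: float = 0.6
    ensemble_repetition: int = 0
    robustness_filter_enabled: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cv"] = dataclasses.asdict(self.cv)
        d["enet"] = dataclasses.asdict(self.enet)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cv = CVConfig(**raw.pop("cv", {}))
    enet = ElasticNetConfig(**raw.pop("enet", {}))
    if "effect_sizes" in raw:
        raw["effect_sizes"] = tuple(raw["effect_sizes"])
    return RunConfig(cv=cv, enet=enet, **raw)


def _simulate_tables(config: RunConfig) -> tuple[FeatureTable, FeatureTable]:
    common = dict(
        n_informative=config.n_informative,
        n_noise=config.n_noise,
        n_redundant_per_block=config.n_redundant_per_block,
        effect_sizes=config.effect_sizes,
        within_block_correlation=config.within_block_correlation,
    )
    discovery = generate_feature_cohort(
        CohortSpec(
            n_patients=config.n_discovery,
            prevalence=config.discovery_prevalence,
            seed=derive_seed(config.base_seed, "simulate", "discovery"),
            **common,
        )
    )
    external = generate_feature_cohort(
        CohortSpec(
            n_patients=config.n_external,
            prevalence=config.external_prevalence,
            seed=derive_seed(config.base_seed, "simulate", "external"),
            **common,
        )
    )
    scale = config.volume_feature_scale
    return (
        attach_volume_proxy(discovery, scale=scale),
        attach_volume_proxy(external, scale=scale),
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Artifacts: feature CSVs, model JSON bundles, the signature report, the
    external metrics report and a manifest with config hash and counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "config_hash": config.config_hash()}

    # --- simulate ---------------------------------------------------------
    discovery, external = _simulate_tables(config)
    discovery.to_csv(out / "discovery_features.csv")
    external.to_csv(out / "external_features.csv")
    manifest["simulate"] = {
        "discovery": {"patients": discovery.n_patients, "features": len(discovery.feature_names),
                      "prevalence": discovery.prevalence},
        "external": {"patients": external.n_patients, "features": len(external.feature_names),
                     "prevalence": external.prevalence},
    }

    # --- extract (imaging demonstration, optional) ------------------------
    if config.simulate_imaging:
        cohort = generate_imaging_cohort(
            config.n_imaging,
            config.discovery_prevalence,
            ResponderShift(),
            seed=derive_seed(config.base_seed, "simulate", "imaging"),
        )
        imaging_features = extract_cohort(cohort)
        imaging_features.to_csv(out / "imaging_features.csv")
        manifest["extract"] = {
            "patients": imaging_features.n_patients,
            "features": len(imaging_features.feature_names),
        }
        if config.robustness_filter_enabled:
            from scipy import ndimage

            from .preprocessing import robustness_filter

            perturbed = [
                (vol, ndimage.binary_erosion(mask) if i % 2 == 0 else ndimage.binary_dilation(mask), label)
                for i, (vol, mask, label) in enumerate(cohort)
            ]
            perturbed_features = extract_cohort(perturbed)
            robust = robustness_filter(
                imaging_features.features, perturbed_features.features
            )
            (out / "robust_features.json").write_text(json.dumps(robust, indent=1))
            manifest["extract"]["robust_features"] = len(robust)

    # --- fit --------------------------------------------------------------
    cv = dataclasses.replace(config.cv, base_seed=derive_seed(config.base_seed, "fit"))
    full = repeat_nested_cv(discovery, cv, config.enet)
    full.metrics.to_csv(out / "discovery_metrics_full.csv")
    (out / "models_full.json").write_text(
        json.dumps([m.to_dict() for m in full.models], indent=1)
    )
    manifest["fit"] = {
        "model_instances": full.n_instances,
        "features_entering": len(discovery.feature_names),
        "mean_outer_auc": float(full.metrics["auc"].mean()),
    }

    # --- signature --------------------------------------------------------
    counts = count_occurrences(full.models, full.feature_names)
    selected = select_relevant(
        counts, full.n_instances, config.occurrence_threshold_fraction
    )
    reduced = refit_reduced(discovery, selected, cv, config.enet)
    reduced.metrics.to_csv(out / "discovery_metrics_reduced.csv")
    report = build_signature_report(full, reduced, selected)
    (out / "signature_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    report.to_frame().to_csv(out / "signature_table.csv", index=False)
    manifest["signature"] = {
        "selected_features": selected,
        "mean_outer_auc_reduced": float(reduced.metrics["auc"].mean()),
    }

    # --- evaluate ---------------------------------------------------------
    rep = config.ensemble_repetition
    ens_full = EnsembleModel.from_run(full.runs[rep])
    ens_reduced = EnsembleModel.from_run(reduced.runs[rep])
    baseline = volumetric_baseline(
        discovery.features["volume_cm3"], discovery.labels, cv, config.enet
    )
    ens_base = EnsembleModel.from_run(baseline.runs[rep])

    evaluation = {}
    for name, ens in [("full", ens_full), ("reduced", ens_reduced), ("volume", ens_base)]:
        pred = ensemble_predict(ens, external)
        pred.to_csv(out / f"external_votes_{name}.csv")
        evaluation[name] = compute_metrics(
            pred["predicted_class"].to_numpy(),
            pred["ensemble_score"].to_numpy(),
            pred["label"].to_numpy(),
        )
    with open(out / "external_metrics.json", "w") as fh:
        json.dump(evaluation, fh, indent=1)
    manifest["evaluate"] = evaluation

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
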