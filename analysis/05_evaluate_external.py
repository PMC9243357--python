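"""External testing: majority-voting ensembles vs the volumetric baseline.

Deploys the 5 outer-fold models of one nested-CV pass as a majority-voting
ensemble on the external cohort — for the full feature set, the reduced
signature set and the volume-only baseline — and compares the imbalance-
aware metric distributions across repetitions with Wilcoxon rank-sum tests
and Holm adjustment. Writes reports under results/external/.
"""

import json
from pathlib import Path

import numpy as np

from crsrad.ensemble import EnsembleModel, ensemble_predict, volumetric_baseline
from crsrad.metrics import compare_metric_distributions, compute_metrics, holm_adjust
from crsrad.model import CVConfig, repeat_nested_cv
from crsrad.signature import count_occurrences, refit_reduced, select_relevant
from crsrad.tables import FeatureTable

N_REPETITIONS = 25
BASE_SEED = 1
OUT = Path("results/external")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    discovery = FeatureTable.from_csv("results/data/discovery_features.csv")
    external = FeatureTable.from_csv("results/data/external_features.csv")
    cv = CVConfig(n_repetitions=N_REPETITIONS, base_seed=BASE_SEED)

    full = repeat_nested_cv(discovery, cv)
    counts = count_occurrences(full.models, full.feature_names)
    selected = select_relevant(counts, full.n_instances, threshold_fraction=0.6)
    reduced = refit_reduced(discovery, selected, cv)
    baseline = volumetric_baseline(discovery.features["volume_cm3"], discovery.labels, cv)

    # one external evaluation per repetition (the error-bar view)
    dists: dict[str, dict[str, list[float]]] = {}
    for name, res in [("full", full), ("reduced", reduced), ("volume", baseline)]:
        dists[name] = {"gmean": [], "npv": [], "auc": []}
        for run in res.runs:
            pred = ensemble_predict(EnsembleModel.from_run(run), external)
            m = compute_metrics(
                pred["predicted_class"].to_numpy(),
                pred["ensemble_score"].to_numpy(),
                pred["label"].to_numpy(),
            )
            for k in dists[name]:
                dists[name][k].append(m[k])

    summary = {}
    for name, per_metric in dists.items():
        summary[name] = {
            k: {"mean": float(np.nanmean(v)), "sd": float(np.nanstd(v))}
            for k, v in per_metric.items()
        }
        print(f"{name:8s} " + "  ".join(
            f"{k} {summary[name][k]['mean']:.3f}+/-{summary[name][k]['sd']:.3f}"
            for k in ("auc", "gmean", "npv")
        ))

    raw_p = [
        compare_metric_distributions(dists["full"][k], dists["volume"][k], paired=True)
        for k in ("gmean", "npv")
    ]
    adj_p = holm_adjust(raw_p)
    comparisons = {
        "full_vs_volume_gmean": {"p": raw_p[0], "p_holm": adj_p[0]},
        "full_vs_volume_npv": {"p": raw_p[1], "p_holm": adj_p[1]},
    }
    for k, v in comparisons.items():
        print(f"{k}: p = {v['p']:.2e} (Holm-adjusted {v['p_holm']:.2e})")

    (OUT / "external_report.json").write_text(
        json.dumps({"metrics": summary, "comparisons": comparisons,
                    "selected_features": selected}, indent=1)
    )


if __name__ == "__main__":
    main()
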