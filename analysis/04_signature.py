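"""Stability selection: occurrence counts, relevant features, reduced refit.

Counts how often each feature carries a non-zero Elastic Net coefficient
across the model instances fitted in 03_fit_nested_cv.py, selects the
features occurring in strictly more than 60% of instances (plus the
force-included tumor volume), refits the pipeline on that reduced set with
identical partitions, and writes the signature table under
results/signature/.
"""

import json
from pathlib import Path

from crsrad.model import CVConfig, FittedModel, repeat_nested_cv
from crsrad.signature import (
    build_signature_report,
    count_occurrences,
    refit_reduced,
    select_relevant,
)
from crsrad.tables import FeatureTable

N_REPETITIONS = 25  # must match 03_fit_nested_cv.py
BASE_SEED = 1
OUT = Path("results/signature")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = FeatureTable.from_csv("results/data/discovery_features.csv")
    cv = CVConfig(n_repetitions=N_REPETITIONS, base_seed=BASE_SEED)

    # the full run (same seeds as 03, so identical partitions)
    full = repeat_nested_cv(table, cv)
    counts = count_occurrences(full.models, full.feature_names)
    selected = select_relevant(counts, full.n_instances, threshold_fraction=0.6)
    print(f"occurrence threshold: > {0.6 * full.n_instances:.0f} of {full.n_instances}")
    print("selected relevant features:", selected)

    reduced = refit_reduced(table, selected, cv)
    reduced.metrics.to_csv(OUT / "discovery_metrics_reduced.csv")
    report = build_signature_report(full, reduced, selected)
    (OUT / "signature_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    frame = report.to_frame()
    frame.to_csv(OUT / "signature_table.csv", index=False)
    print(frame.to_string(index=False))
    print(
        f"mean outer AUC: full {full.metrics['auc'].mean():.3f}, "
        f"reduced {reduced.metrics['auc'].mean():.3f}"
    )


if __name__ == "__main__":
    main()
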