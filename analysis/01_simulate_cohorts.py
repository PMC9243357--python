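"""Simulate the study cohorts.

Generates the synthetic stand-ins for the two patient cohorts — a discovery
feature cohort of 61 patients at 41% complete response (CRS3) and an
external cohort of 48 patients at 21% — plus a small imaging cohort of
lesion phantoms whose responders have more elongated lesions with a smaller
least axis. Writes feature CSVs and a NIfTI phantom directory under
results/data/.
"""

import numpy as np

from crsrad._seeds import derive_seed
from crsrad.synthetic import (
    CohortSpec,
    ResponderShift,
    attach_volume_proxy,
    generate_feature_cohort,
    generate_imaging_cohort,
    write_imaging_cohort,
)

BASE_SEED = 20260928
OUT = "results/data"


def main() -> None:
    from pathlib import Path

    out = Path(OUT)
    out.mkdir(parents=True, exist_ok=True)

    common = dict(
        n_informative=5,
        effect_sizes=(0.7, 1.0, -1.0, 1.0, -1.0),
        n_noise=10,
        n_redundant_per_block=1,
        within_block_correlation=0.95,
    )
    discovery = attach_volume_proxy(
        generate_feature_cohort(
            CohortSpec(n_patients=61, prevalence=0.41, seed=derive_seed(BASE_SEED, "disc"), **common)
        )
    )
    external = attach_volume_proxy(
        generate_feature_cohort(
            CohortSpec(n_patients=48, prevalence=0.21, seed=derive_seed(BASE_SEED, "ext"), **common)
        )
    )
    discovery.to_csv(out / "discovery_features.csv")
    external.to_csv(out / "external_features.csv")
    print(
        f"discovery: {discovery.n_patients} patients, "
        f"{len(discovery.feature_names)} features, "
        f"{discovery.labels.sum()} complete responders ({discovery.prevalence:.0%})"
    )
    print(
        f"external:  {external.n_patients} patients, "
        f"{external.labels.sum()} complete responders ({external.prevalence:.0%})"
    )

    cohort = generate_imaging_cohort(
        8, prevalence=0.4, responder_shift=ResponderShift(), seed=derive_seed(BASE_SEED, "img")
    )
    manifest = write_imaging_cohort(cohort, out / "phantoms")
    print(f"imaging: {len(manifest)} phantoms written to {out/'phantoms'}")


if __name__ == "__main__":
    main()
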