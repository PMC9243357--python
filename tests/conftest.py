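"""Shared fixtures: tiny deterministic grids, phantoms and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from crsrad.images import CTVolume
from crsrad.synthetic import CohortSpec, PhantomSpec, generate_feature_cohort, generate_lesion_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A textured ellipsoidal lesion with both inclusion types."""
    spec = PhantomSpec(
        grid_shape=(32, 36, 36),
        semi_axes_mm=(11.0, 9.0, 7.0),
        hypodense_fraction=0.08,
        hyperdense_fraction=0.03,
        seed=11,
    )
    return generate_lesion_phantom(spec)


@pytest.fixture(scope="session")
def flat_lesion():
    """A constant-intensity spherical lesion (degenerate texture)."""
    spec = PhantomSpec(
        grid_shape=(26, 26, 26),
        semi_axes_mm=(9.0, 9.0, 9.0),
        soft_tissue_hu_std=0.0,
        hypodense_fraction=0.0,
        hyperdense_fraction=0.0,
        seed=3,
    )
    return generate_lesion_phantom(spec)


@pytest.fixture(scope="session")
def toy_grid():
    """A 4x4x4 integer gray-level grid with a full mask, for matrix oracles."""
    rng = np.random.default_rng(42)
    levels = rng.integers(1, 5, size=(4, 4, 4)).astype(np.int32)
    mask = np.ones((4, 4, 4), dtype=bool)
    return levels, mask, 4


@pytest.fixture(scope="session")
def toy_grid_masked():
    """A 4x4x4 grid with a ragged mask, exercising boundary handling."""
    rng = np.random.default_rng(7)
    levels = rng.integers(1, 4, size=(4, 4, 4)).astype(np.int32)
    mask = rng.uniform(size=(4, 4, 4)) < 0.7
    mask[0, 0, 0] = True  # keep non-empty
    levels[~mask] = 0
    return levels, mask, 3


@pytest.fixture(scope="session")
def discovery_table():
    """A study-sized discovery cohort: 61 patients at 41% prevalence."""
    return generate_feature_cohort(CohortSpec(n_patients=61, prevalence=0.41, seed=5))
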