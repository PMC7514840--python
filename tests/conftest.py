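"""Shared fixtures: phantom patches and cohort feature tables.

The large cohort (15 patients, ~900 candidates, well-separated classes)
is session-scoped because several suites reuse it; everything is generated
at test time from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glandcraft.features.extract import extract_table
from glandcraft.phantom import PhantomSpec, generate_cohort, generate_patch
from glandcraft.selection import FeatureTable

COHORT_SEED = 7


def small_spec(**overrides) -> PhantomSpec:
    base = dict(patch_size=512, glands_per_patch=9, n_patients=3,
                patches_per_patient=1, seed=3)
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def phantom_patch():
    """One mixed-class phantom patch with truth maps."""
    return generate_patch(small_spec(), "pat000", 3)


@pytest.fixture(scope="session")
def study_cohort():
    """The study-scale cohort: 15 patients, ~900 candidates."""
    spec = PhantomSpec(patch_size=512, n_patients=15, patches_per_patient=7,
                       glands_per_patch=9, seed=COHORT_SEED)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def study_features(study_cohort) -> pd.DataFrame:
    return extract_table(study_cohort, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def study_table(study_features) -> FeatureTable:
    return FeatureTable.from_dataframe(study_features)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
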