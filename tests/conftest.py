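"""Shared fixtures.

The expensive fixtures (feature tables over a small cohort) are
session-scoped and shared between the module tests and the acceptance
suite; the cohort size is kept small so the whole suite stays fast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from radrobust.features import FeatureTable, extract_case_features, extract_feature_table
from radrobust.phantoms import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    perturb_mask,
)
from radrobust.segmentation import segment_cohort

warnings.filterwarnings("ignore", message="LoG sigma")


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_phantom(PhantomSpec(noise_sd=0.0, heterogeneity_amplitude=0.0), seed=1)


@pytest.fixture(scope="session")
def noisy_case():
    return generate_phantom(PhantomSpec(), seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort (7 low / 5 high) at the default study conditions."""
    return generate_cohort(CohortSpec(n_low=7, n_high=5, seed=11))


@pytest.fixture(scope="session")
def segmentations(small_cohort):
    return segment_cohort(small_cohort, seed=5)


@pytest.fixture(scope="session")
def method_tables(small_cohort, segmentations):
    """The three per-method 1781-column feature tables."""
    return extract_feature_table(small_cohort, segmentations)


def _jitter_tables(cohort, amplitude_mm: float, n_reps: int = 3):
    """Feature tables from ``n_reps`` independently jittered truth masks."""
    labels = pd.Series({c.subject_id: c.label for c in cohort})
    tables = {}
    for rep in range(n_reps):
        rows = {}
        for i, case in enumerate(cohort):
            mask = perturb_mask(
                case.truth_mask, case.spacing, amplitude_mm, seed=1000 * rep + i
            )
            rows[case.subject_id] = extract_case_features(case.image, mask, case.spacing)
        data = pd.DataFrame(rows).T
        tables[f"jitter{rep}"] = FeatureTable(data, labels.loc[data.index], f"jitter{rep}")
    return tables


@pytest.fixture(scope="session")
def jitter_tables_by_amplitude(small_cohort):
    """Three-replicate jitter tables at 1, 2 and 4 mm (images fixed)."""
    return {amp: _jitter_tables(small_cohort, amp) for amp in (1.0, 2.0, 4.0)}


@pytest.fixture(scope="session")
def synthetic_feature_tables():
    """Random-valued tables with the real 1781-column schema (no imaging).

    Useful for schema-level robustness tests (grouping totals, band
    frequencies) without paying for extraction.
    """
    from radrobust.features import feature_names

    rng = np.random.default_rng(3)
    names = feature_names()
    subjects = [f"S{i:03d}" for i in range(10)]
    labels = pd.Series(["low"] * 6 + ["high"] * 4, index=subjects)
    base = rng.normal(size=(10, len(names)))
    tables = {}
    for j, method in enumerate(("manual", "thresholding", "region_growing")):
        data = pd.DataFrame(
            base + 0.1 * rng.normal(size=base.shape), index=subjects, columns=names
        )
        tables[method] = FeatureTable(data, labels, method)
    return tables
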