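import numpy as np
import pytest

from sarcomics.preprocess import (
    filter_completeness,
    knn_impute,
    log2_reference_ratio,
    median_center_rows,
    standardize_columns,
)
from sarcomics.synthetic import CohortConfig, generate_raw_plexes


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by downstream tests."""
    config = CohortConfig(
        n_samples=60,
        n_proteins=300,
        n_subtypes=3,
        subtype_effect=1.5,
        n_marker_proteins_per_subtype=25,
        module_sizes=(40, 35),
        plex_dropout_rate=0.1,
        missing_rate=0.01,
        survival_betas={"subtype:ST1": np.log(2.0)},
        seed=11,
    )
    raw, truth = generate_raw_plexes(config)
    return config, raw, truth


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    _, raw, _ = small_cohort
    ratio = log2_reference_ratio(raw)
    filtered = filter_completeness(ratio)
    imputed = knn_impute(filtered, k=5)
    return standardize_columns(median_center_rows(imputed))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
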