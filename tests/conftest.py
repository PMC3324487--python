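import numpy as np
import pandas as pd
import pytest

from uripept.synthetic import (
    StudyConfig,
    generate_study,
    generate_two_group_study,
    make_reference_set,
)


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(
        n_peptides=120,
        n_markers_up=8,
        n_markers_down=4,
        doses=(0, 150, 300),
        days=(1, 3, 10, 44),
        n_per_cell=3,
        n_internal_standards=20,
        n_housekeeping=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_refs(small_study):
    _, _, truth = small_study
    return make_reference_set(truth)


@pytest.fixture(scope="session")
def two_group():
    cfg = StudyConfig(
        n_peptides=150,
        n_markers_up=15,
        n_markers_down=10,
        n_internal_standards=20,
        n_housekeeping=20,
        missing_rate=0.05,
        seed=11,
    )
    samples, design, truth = generate_two_group_study(cfg, n_control=12, n_case=12)
    return cfg, samples, design, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
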