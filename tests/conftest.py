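"""Shared fixtures: a small, fast synthetic cohort and its dynamic tensors."""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sednet import (
    SyntheticConfig,
    WindowSpec,
    build_cohort_tensors,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CONFIG = SyntheticConfig(
    n_subjects=12,
    n_regions=24,
    n_timepoints=60,
    n_components=2,
    effect_size=2.0,
    seed=5,
)
SMALL_WINDOW = WindowSpec(length_trs=20)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects x 24 regions x 60 TRs with a strong planted effect."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_tensors(small_cohort):
    series, _, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 20-TR window is below the f_min guard
        return build_cohort_tensors(series, SMALL_WINDOW, density=0.10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
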