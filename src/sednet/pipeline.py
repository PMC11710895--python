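"""End-to-end orchestration helpers tying the pipeline stages together.

These wrappers exist so the analysis drivers, the tests and the acceptance
script all execute the identical sequence: time series -> dynamic connectivity
tensors -> median-split labels -> shared split scheme -> repeated CV (or its
permutation null).
"""

from __future__ import annotations

import numpy as np

from .behavioral import GroupAssignment, behavior_records, median_split_groups
from .dynamic_networks import (
    DynamicConnectivityTensor,
    WindowSpec,
    build_dynamic_networks,
)
from .prediction import (
    AggregateMetrics,
    PipelineConfig,
    RepeatedCVResult,
    SplitScheme,
    make_split_scheme,
    run_permutation_null,
    run_repeated_cv,
)
from .timeseries_io import CohortManifest, SubjectTimeSeries


def build_cohort_tensors(
    series_list: list[SubjectTimeSeries],
    window: WindowSpec | None = None,
    density: float = 0.10,
) -> dict[str, DynamicConnectivityTensor]:
    """Build every subject's thresholded sliding-window correlation tensor."""
    window = window or WindowSpec()
    return {
        ts.subject_id: build_dynamic_networks(ts, window, density=density)
        for ts in series_list
    }


def cohort_labels(manifest: CohortManifest, measure: str) -> GroupAssignment:
    """Median-split low/high-change labels for one measure from the manifest."""
    return median_split_groups(behavior_records(manifest, measure))


def predict_measure(
    tensors_by_subject: dict[str, DynamicConnectivityTensor],
    manifest: CohortManifest,
    measure: str,
    scheme: SplitScheme | None = None,
    n_splits: int = 100,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[RepeatedCVResult, GroupAssignment, SplitScheme]:
    """Run the full repeated-subsampling prediction for ``st`` or ``ns``."""
    labels = cohort_labels(manifest, measure)
    if scheme is None:
        n = len(labels.labels)
        n_test = max(2, int(round(n * 8 / 36 / 2)) * 2)
        scheme = make_split_scheme(
            labels, n_splits=n_splits, n_train=n - n_test, n_test=n_test, seed=seed
        )
    result = run_repeated_cv(tensors_by_subject, labels, scheme, config)
    return result, labels, scheme


def null_measure(
    tensors_by_subject: dict[str, DynamicConnectivityTensor],
    manifest: CohortManifest,
    measure: str,
    scheme: SplitScheme,
    seed: int,
    config: PipelineConfig | None = None,
) -> AggregateMetrics:
    """Chance-level permutation control for one measure on a shared scheme."""
    labels = cohort_labels(manifest, measure)
    return run_permutation_null(tensors_by_subject, labels, scheme, seed, config)
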