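"""Linear-SVM group prediction over repeated balanced train/test subsamplings.

The cohort (36 subjects, 18 low-change / 18 high-change) is split 100 times
into balanced training (14 + 14) and testing (4 + 4) subsets. Per split, the
connectivity-mode basis is fitted on the 28 training tensors only, both
subsets are projected and time-averaged to R^2 feature vectors, and a linear
soft-margin SVM (C = 1, no feature scaling, no tuning) separates the groups.
The low-change group is the positive class, so *sensitivity* is recall on
low-change and *specificity* recall on high-change subjects. Accuracy,
sensitivity, specificity and a logistic cross-entropy on the raw decision
values are averaged (mean ± sample std) over the splits, and the per-split
weight vectors are averaged and unflattened into the R x R weight matrix whose
diagonal carries single-component features and off-diagonal the component
interactions.

The chance-level control re-runs the identical machinery with the whole
cohort's labels randomly re-permuted (balanced) per split, reusing the same
split memberships, and should sit at ~50% accuracy.

To keep the per-split refits cheap, two identities are used: the basis depends
on the training stack only through the sum of per-subject Gram matrices, and
time-averaging commutes with projection (mean_t U^T C_t U = U^T mean_t(C_t) U),
so per-subject Grams and time-mean matrices are precomputed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .behavioral import GroupAssignment
from .dynamic_networks import DynamicConnectivityTensor
from .errors import ConfigurationError, DimensionError, ValidationError
from .tensor_decomposition import (
    ConnectivityBasis,
    ReducedFeatures,
    basis_from_gram,
    mode1_gram,
    select_rank,
)

_PROB_CLIP = 1e-12


@dataclass(frozen=True)
class SplitScheme:
    """Reusable balanced train/test subsamplings (shared across st/ns/nulls)."""

    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test) ids
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)


@dataclass
class ClassifierModel:
    """Linear decision rule: positive decision value -> low-change class."""

    weights: np.ndarray
    bias: float
    positive_class: str = "low"

    def decision(self, features: np.ndarray) -> np.ndarray:
        return np.atleast_2d(features) @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> list[str]:
        negative = "high" if self.positive_class == "low" else "low"
        return [
            self.positive_class if d >= 0 else negative
            for d in self.decision(features)
        ]


@dataclass(frozen=True)
class SplitMetrics:
    """Test-set performance of one split, percentages (cross-entropy in nats)."""

    accuracy: float
    sensitivity: float
    specificity: float
    cross_entropy: float


@dataclass
class AggregateMetrics:
    """Mean and sample (n-1) std of each metric across the splits run."""

    mean: dict[str, float]
    std: dict[str, float]
    n_splits: int
    per_split: list[SplitMetrics] = field(repr=False, default_factory=list)


@dataclass
class WeightMatrixSummary:
    """Mean SVM weight vectors across splits, unflattened row-major to R x R."""

    matrix: np.ndarray
    n_splits: int


@dataclass
class RepeatedCVResult:
    """Everything run_repeated_cv produces for one measure."""

    metrics: AggregateMetrics
    weight_summary: WeightMatrixSummary
    bases: list[ConnectivityBasis]
    rank: int


@dataclass(frozen=True)
class PipelineConfig:
    """Per-split reduction + classifier settings.

    ``rank=None`` selects, per run, the maximum over splits of each split's
    minimal variance-capturing rank (keeping the feature length constant so
    weight matrices can be averaged); an integer reproduces a fixed-R run
    (the study used R = 17).
    """

    variance_threshold: float = 0.85
    rank: int | None = None
    svm_cost: float = 1.0
    positive_class: str = "low"


def make_split_scheme(
    labels: GroupAssignment,
    n_splits: int = 100,
    n_train: int = 28,
    n_test: int = 8,
    seed: int = 0,
) -> SplitScheme:
    """Draw balanced random train/test partitions, reproducible from ``seed``."""
    low, high = labels.low_ids, labels.high_ids
    if len(low) != len(high):
        raise ConfigurationError(
            f"balanced subsampling needs equal groups, got {len(low)} low / {len(high)} high"
        )
    if n_train % 2 or n_test % 2:
        raise ConfigurationError("n_train and n_test must both be even")
    if n_train + n_test != len(low) + len(high):
        raise ConfigurationError(
            f"n_train + n_test = {n_train + n_test} != cohort size {len(low) + len(high)}"
        )
    per_class_train = n_train // 2
    if per_class_train > len(low):
        raise ConfigurationError("not enough subjects per class for the training half")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        train: list[str] = []
        test: list[str] = []
        for group in (low, high):
            perm = rng.permutation(len(group))
            train.extend(group[i] for i in perm[:per_class_train])
            test.extend(group[i] for i in perm[per_class_train:])
        splits.append((tuple(sorted(train)), tuple(sorted(test))))
    return SplitScheme(splits=tuple(splits), seed=seed)


def train_linear_svm(
    features: list[ReducedFeatures],
    labels: GroupAssignment | dict[str, str],
    cost: float = 1.0,
    positive_class: str = "low",
) -> ClassifierModel:
    """Fit a soft-margin linear SVM (hinge loss, L2, no feature scaling)."""
    label_map = labels.labels if isinstance(labels, GroupAssignment) else labels
    x = np.array([f.features for f in features])
    if x.ndim != 2:
        raise DimensionError("feature vectors differ in length")
    y = np.array(
        [1 if label_map[f.subject_id] == positive_class else -1 for f in features]
    )
    if len(np.unique(y)) < 2:
        raise ValidationError("training set contains a single class")
    svm = SVC(kernel="linear", C=cost)
    svm.fit(x, y)
    # sklearn orders classes ascending ([-1, +1]), so positive decision -> +1.
    return ClassifierModel(
        weights=svm.coef_[0].copy(),
        bias=float(svm.intercept_[0]),
        positive_class=positive_class,
    )


def evaluate_split(
    model: ClassifierModel,
    test_features: list[ReducedFeatures],
    labels: GroupAssignment | dict[str, str],
    strict: bool = True,
) -> SplitMetrics:
    """Score one test set: accuracy, per-class recalls, logistic cross-entropy.

    With ``strict`` (default) a test set missing one class is an error; with
    ``strict=False`` the missing class's recall is NaN (used by permutation
    nulls, where a random relabeling can empty a class in a small test set).
    """
    label_map = labels.labels if isinstance(labels, GroupAssignment) else labels
    pos = model.positive_class
    x = np.array([f.features for f in test_features])
    truth = np.array([label_map[f.subject_id] == pos for f in test_features])
    if strict and (truth.all() or not truth.any()):
        raise ValidationError("test set is missing one of the classes")
    decision = model.decision(x)
    predicted_pos = decision >= 0

    correct = predicted_pos == truth
    accuracy = 100.0 * correct.mean()
    sensitivity = 100.0 * correct[truth].mean() if truth.any() else float("nan")
    specificity = 100.0 * correct[~truth].mean() if (~truth).any() else float("nan")

    p = 1.0 / (1.0 + np.exp(-decision))
    p = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
    y = truth.astype(float)
    cross_entropy = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return SplitMetrics(
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        cross_entropy=cross_entropy,
    )


def _aggregate(per_split: list[SplitMetrics]) -> AggregateMetrics:
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for name in ("accuracy", "sensitivity", "specificity", "cross_entropy"):
        vals = np.array([getattr(m, name) for m in per_split], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean[name] = float(vals.mean())
        std[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return AggregateMetrics(mean=mean, std=std, n_splits=len(per_split), per_split=per_split)


class _SubjectCache:
    """Per-subject mode-1 Grams and time-mean matrices, computed once."""

    def __init__(self, tensors_by_subject: dict[str, DynamicConnectivityTensor]):
        self.grams = {
            sid: mode1_gram(t.data) for sid, t in tensors_by_subject.items()
        }
        self.time_means = {
            sid: t.data.mean(axis=2) for sid, t in tensors_by_subject.items()
        }

    def basis_for(
        self, train_ids: tuple[str, ...], config: PipelineConfig, rank: int | None
    ) -> ConnectivityBasis:
        gram = sum(self.grams[sid] for sid in train_ids)
        return basis_from_gram(
            gram, config.variance_threshold, list(train_ids), rank=rank
        )

    def features_for(self, sid: str, basis: ConnectivityBasis) -> ReducedFeatures:
        u = basis.basis
        reduced = u.T @ self.time_means[sid] @ u
        return ReducedFeatures(subject_id=sid, reduced=reduced, features=reduced.ravel())


def _check_coverage(
    tensors_by_subject: dict[str, DynamicConnectivityTensor], scheme: SplitScheme
) -> None:
    needed = {sid for train, test in scheme.splits for sid in train + test}
    missing = sorted(needed - set(tensors_by_subject))
    if missing:
        raise ValidationError(f"missing dynamic tensors for subjects: {missing}")


def _run_splits(
    cache: _SubjectCache,
    scheme: SplitScheme,
    labels_per_split: list[dict[str, str]],
    config: PipelineConfig,
    strict_eval: bool = True,
) -> tuple[list[SplitMetrics], list[np.ndarray], list[ConnectivityBasis], int]:
    """Shared engine for the main analysis and the permutation null."""
    if config.rank is not None:
        rank = config.rank
    else:
        # Run-level R = max over splits of each split's minimal rank, so the
        # feature length is constant and weight matrices can be averaged.
        rank = 1
        for train_ids, _ in scheme.splits:
            gram = sum(cache.grams[sid] for sid in train_ids)
            eigvals = np.clip(np.linalg.eigvalsh(gram)[::-1], 0.0, None)
            rank = max(rank, select_rank(np.sqrt(eigvals), config.variance_threshold))

    per_split: list[SplitMetrics] = []
    weight_vectors: list[np.ndarray] = []
    bases: list[ConnectivityBasis] = []
    for (train_ids, test_ids), labels in zip(scheme.splits, labels_per_split):
        basis = cache.basis_for(train_ids, config, rank)
        train_feats = [cache.features_for(sid, basis) for sid in train_ids]
        test_feats = [cache.features_for(sid, basis) for sid in test_ids]
        model = train_linear_svm(
            train_feats, labels, cost=config.svm_cost, positive_class=config.positive_class
        )
        per_split.append(evaluate_split(model, test_feats, labels, strict=strict_eval))
        weight_vectors.append(model.weights)
        bases.append(basis)
    return per_split, weight_vectors, bases, rank


def run_repeated_cv(
    tensors_by_subject: dict[str, DynamicConnectivityTensor],
    labels: GroupAssignment,
    scheme: SplitScheme,
    config: PipelineConfig | None = None,
) -> RepeatedCVResult:
    """Full repeated-subsampling analysis for one behavioral measure.

    Per split: fit the connectivity basis on the training tensors only,
    project and time-average both subsets, train the linear SVM, and score the
    test subjects. Nothing fitted ever sees a test subject.
    """
    config = config or PipelineConfig()
    _check_coverage(tensors_by_subject, scheme)
    cache = _SubjectCache(tensors_by_subject)
    labels_per_split = [labels.labels] * scheme.n_splits
    per_split, weight_vectors, bases, rank = _run_splits(
        cache, scheme, labels_per_split, config
    )
    return RepeatedCVResult(
        metrics=_aggregate(per_split),
        weight_summary=summarize_weight_matrix(weight_vectors, rank),
        bases=bases,
        rank=rank,
    )


def run_permutation_null(
    tensors_by_subject: dict[str, DynamicConnectivityTensor],
    labels: GroupAssignment,
    scheme: SplitScheme,
    seed: int,
    config: PipelineConfig | None = None,
    per_split_permutation: bool = True,
) -> AggregateMetrics:
    """Chance-level control: relabel the whole cohort at random, then predict.

    Per split a balanced random relabeling of all subjects is drawn (half low,
    half high), and that split proceeds exactly as in :func:`run_repeated_cv`
    with the same train/test memberships. ``per_split_permutation=False`` draws
    a single relabeling for the whole run instead.
    """
    config = config or PipelineConfig()
    _check_coverage(tensors_by_subject, scheme)
    cache = _SubjectCache(tensors_by_subject)
    subjects = sorted(labels.labels)
    n_low = len(labels.low_ids)
    rng = np.random.default_rng(seed)

    def draw() -> dict[str, str]:
        perm = rng.permutation(len(subjects))
        relabeled = {subjects[i]: "low" for i in perm[:n_low]}
        relabeled.update({subjects[i]: "high" for i in perm[n_low:]})
        return relabeled

    if per_split_permutation:
        labels_per_split = [draw() for _ in range(scheme.n_splits)]
    else:
        labels_per_split = [draw()] * scheme.n_splits
    per_split, _, _, _ = _run_splits(
        cache, scheme, labels_per_split, config, strict_eval=False
    )
    return _aggregate(per_split)


def summarize_weight_matrix(
    weight_vectors: list[np.ndarray], rank: int
) -> WeightMatrixSummary:
    """Average per-split weight vectors; unflatten row-major to rank x rank."""
    if not weight_vectors:
        raise ValidationError("no weight vectors to summarize")
    for w in weight_vectors:
        if w.shape != (rank * rank,):
            raise DimensionError(
                f"weight vector length {w.shape} != rank^2 = {rank * rank}"
            )
    mean = np.mean(weight_vectors, axis=0).reshape(rank, rank)
    return WeightMatrixSummary(matrix=mean, n_splits=len(weight_vectors))
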