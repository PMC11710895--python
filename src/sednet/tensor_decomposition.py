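"""HOSVD reduction of stacked connectivity tensors and component reconstruction.

The training subjects' dynamic connectivity tensors are concatenated into a
fourth-order tensor C in R^{N x N x T x M}. The connectivity-mode factor U (the
left singular vectors of the mode-1 unfolding, an N x (N*T*M) matrix) is
computed from the N x N Gram matrix sum_{t,m} C_tm C_tm^T via a symmetric
eigendecomposition — algebraically identical to the unfolding SVD but never
materializing the unfolding. Because every slice is symmetric, the mode-2
factor equals the mode-1 factor and is not computed separately; the time and
subject modes are not reduced.

The reduced rank R is the smallest number of leading components whose
cumulative squared singular values capture at least the variance threshold
(85% by default). Each subject's slices are projected as U^T C_t U and averaged
over time, giving an R x R matrix flattened row-major into an R^2 feature
vector (289 at R = 17).

Components are reconstructed from single basis columns: component i maps to the
rank-1 edge matrix u_i u_i^T, ranked by normalized variance sigma_i^2 /
sigma_1^2, and summarized by its top-1% strongest edges and the per-region
counts of retained edges (node degree).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamic_networks import DynamicConnectivityTensor, _round_half_away
from .errors import ConfigurationError, DimensionError, ValidationError


@dataclass
class StackedConnectivityTensor:
    """Fourth-order tensor (N, N, T, M) of M subjects' connectivity stacks."""

    data: np.ndarray
    subject_ids: list[str]

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]


@dataclass
class ConnectivityBasis:
    """Orthonormal connectivity-mode basis from the training stack.

    ``basis`` holds the leading ``rank`` columns; ``singular_values`` and
    ``variance_fractions`` (cumulative) cover all N modes.
    """

    basis: np.ndarray  # (N, R)
    singular_values: np.ndarray  # (N,)
    variance_fractions: np.ndarray  # (N,) cumulative, last == 1
    rank: int
    training_ids: list[str]

    @property
    def n_regions(self) -> int:
        return self.basis.shape[0]


@dataclass
class ReducedFeatures:
    """Per-subject time-averaged reduced connectivity and its flattening."""

    subject_id: str
    reduced: np.ndarray  # (R, R), symmetric
    features: np.ndarray  # (R*R,) row-major


@dataclass
class ComponentMap:
    """One connectivity component rendered as a rank-1 edge map."""

    index: int  # 1-based
    loading: np.ndarray  # (N,)
    edge_matrix: np.ndarray  # (N, N) = loading outer loading
    normalized_variance: float
    top_edges: list[tuple[int, int, float]] | None = None  # 1-based region ids
    node_degrees: np.ndarray | None = None


def stack_training_tensors(
    tensors: list[DynamicConnectivityTensor],
) -> StackedConnectivityTensor:
    """Concatenate subject tensors along a new 4th (subject) mode."""
    if len(tensors) < 2:
        raise ConfigurationError("need at least 2 tensors to stack")
    ref = tensors[0]
    for t in tensors[1:]:
        if t.data.shape != ref.data.shape:
            raise DimensionError(
                f"tensor shape mismatch: {t.subject_id!r} has {t.data.shape}, "
                f"{ref.subject_id!r} has {ref.data.shape}"
            )
        if t.density != ref.density:
            raise DimensionError("tensors mix densities")
    data = np.stack([t.data for t in tensors], axis=3)
    return StackedConnectivityTensor(data=data, subject_ids=[t.subject_id for t in tensors])


def _fix_column_signs(u: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic signs)."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def basis_from_gram(
    gram: np.ndarray,
    variance_threshold: float,
    training_ids: list[str],
    rank: int | None = None,
) -> ConnectivityBasis:
    """Eigendecompose the mode-1 Gram matrix into a ConnectivityBasis.

    ``gram`` must equal A A^T for the mode-1 unfolding A; its eigenvalues are
    the squared singular values of A.
    """
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_column_signs(eigvecs[:, order])
    total = eigvals.sum()
    if total <= 0:
        raise ValidationError("degenerate input: all-zero connectivity stack")
    fractions = np.cumsum(eigvals) / total
    fractions[-1] = 1.0
    singular_values = np.sqrt(eigvals)
    r = rank if rank is not None else select_rank(singular_values, variance_threshold)
    if not 1 <= r <= gram.shape[0]:
        raise ConfigurationError(f"rank {r} outside 1..{gram.shape[0]}")
    return ConnectivityBasis(
        basis=eigvecs[:, :r],
        singular_values=singular_values,
        variance_fractions=fractions,
        rank=r,
        training_ids=list(training_ids),
    )


def mode1_gram(data: np.ndarray) -> np.ndarray:
    """Gram matrix of the mode-1 unfolding: sum over all slices of C C^T."""
    if data.ndim == 3:
        flat = data.reshape(data.shape[0], -1)
    elif data.ndim == 4:
        flat = data.reshape(data.shape[0], -1)
    else:
        raise DimensionError(f"expected 3-D or 4-D connectivity data, got {data.ndim}-D")
    return flat @ flat.T


def fit_connectivity_basis(
    stack: StackedConnectivityTensor,
    variance_threshold: float = 0.85,
    rank: int | None = None,
) -> ConnectivityBasis:
    """Fit the connectivity-mode HOSVD basis on a training stack.

    ``rank=None`` selects the minimal R capturing ``variance_threshold`` of the
    squared-singular-value mass; an integer fixes R (the study fixed R = 17).
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ConfigurationError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )
    gram = mode1_gram(stack.data)
    return basis_from_gram(gram, variance_threshold, stack.subject_ids, rank=rank)


def select_rank(singular_values: np.ndarray, variance_threshold: float) -> int:
    """Smallest R whose cumulative squared-singular-value fraction >= threshold."""
    sv = np.asarray(singular_values, dtype=float)
    if sv.size == 0 or sv.max() <= 0:
        raise ValidationError("need at least one positive singular value")
    if np.any(np.diff(sv) > 1e-12 * sv.max()):
        raise ValidationError("singular values must be non-increasing")
    if not 0.0 < variance_threshold <= 1.0:
        raise ConfigurationError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )
    energy = sv**2
    fractions = np.cumsum(energy) / energy.sum()
    if variance_threshold >= 1.0:
        return int(np.flatnonzero(sv > 0)[-1] + 1)
    return int(np.searchsorted(fractions, variance_threshold) + 1)


def project_subject(
    tensor: DynamicConnectivityTensor, basis: ConnectivityBasis
) -> np.ndarray:
    """Project every time slice onto the basis: C_t -> U^T C_t U, giving (R,R,T)."""
    if tensor.n_regions != basis.n_regions:
        raise DimensionError(
            f"tensor has {tensor.n_regions} regions, basis {basis.n_regions}"
        )
    u = basis.basis
    return np.einsum("ir,ijt,js->rst", u, tensor.data, u, optimize=True)


def time_average_features(reduced: np.ndarray, subject_id: str) -> ReducedFeatures:
    """Average the reduced stack over time; flatten row-major to R^2 features."""
    reduced = np.asarray(reduced, dtype=float)
    if reduced.ndim != 3 or reduced.shape[0] != reduced.shape[1]:
        raise DimensionError(f"expected (R, R, T) array, got shape {reduced.shape}")
    mean = reduced.mean(axis=2)
    return ReducedFeatures(subject_id=subject_id, reduced=mean, features=mean.ravel())


def normalized_variances(basis: ConnectivityBasis) -> np.ndarray:
    """Component variances relative to the leading one: nv_i = sigma_i^2 / sigma_1^2."""
    sv = basis.singular_values
    if sv[0] <= 0:
        raise ValidationError("leading singular value must be positive")
    return (sv / sv[0]) ** 2


def reconstruct_component(basis: ConnectivityBasis, index: int) -> ComponentMap:
    """Render component ``index`` (1-based) as its rank-1 edge matrix."""
    if not 1 <= index <= basis.rank:
        raise ConfigurationError(f"component index {index} outside 1..{basis.rank}")
    loading = basis.basis[:, index - 1]
    return ComponentMap(
        index=index,
        loading=loading,
        edge_matrix=np.outer(loading, loading),
        normalized_variance=float(normalized_variances(basis)[index - 1]),
    )


def average_components_across_splits(
    bases: list[ConnectivityBasis], index: int
) -> ComponentMap:
    """Average one component's loading across split bases, sign-aligned.

    Singular vectors are sign-ambiguous, so each basis's column is flipped to a
    non-negative dot product with the first basis's column before averaging;
    the mean is renormalized to unit length. The attached normalized variance
    is the mean of the per-basis values.
    """
    if not bases:
        raise ConfigurationError("need at least one basis")
    n = bases[0].n_regions
    for b in bases:
        if b.n_regions != n:
            raise DimensionError("bases differ in region count")
        if b.rank < index:
            raise ConfigurationError(f"basis rank {b.rank} < component index {index}")
    ref = bases[0].basis[:, index - 1]
    acc = np.zeros(n)
    nv = 0.0
    for b in bases:
        col = b.basis[:, index - 1]
        if col @ ref < 0:
            col = -col
        acc += col
        nv += float(normalized_variances(b)[index - 1])
    mean = acc / len(bases)
    norm = np.linalg.norm(mean)
    if norm == 0:
        raise ValidationError(f"component {index} loadings cancel across splits")
    loading = mean / norm
    return ComponentMap(
        index=index,
        loading=loading,
        edge_matrix=np.outer(loading, loading),
        normalized_variance=nv / len(bases),
    )


def threshold_component_edges(
    component: ComponentMap, top_fraction: float = 0.01
) -> ComponentMap:
    """Keep the top fraction of strongest (|weight|) component edges.

    Returns a copy with ``top_edges`` — exactly round(top_fraction * N(N-1)/2)
    (region_i, region_j, weight) triples, 1-based, ties broken by ascending
    (row, col) — and ``node_degrees``, the per-region retained-edge counts.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ConfigurationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    em = component.edge_matrix
    n = em.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    vals = em[rows, cols]
    k_keep = _round_half_away(top_fraction * len(vals))
    order = np.lexsort((cols, rows, -np.abs(vals)))
    keep = order[:k_keep]
    top_edges = [
        (int(rows[i]) + 1, int(cols[i]) + 1, float(vals[i])) for i in keep
    ]
    degrees = np.zeros(n, dtype=int)
    for i, j, _ in top_edges:
        degrees[i - 1] += 1
        degrees[j - 1] += 1
    return replace(component, top_edges=top_edges, node_degrees=degrees)
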