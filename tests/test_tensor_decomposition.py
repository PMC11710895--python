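"""HOSVD basis fitting, rank selection, projection, component reconstruction."""

import numpy as np
import pytest

from sednet import (
    ConfigurationError,
    DimensionError,
    ValidationError,
    average_components_across_splits,
    fit_connectivity_basis,
    normalized_variances,
    project_subject,
    reconstruct_component,
    select_rank,
    stack_training_tensors,
    threshold_component_edges,
    time_average_features,
)
from sednet.dynamic_networks import DynamicConnectivityTensor, WindowSpec
from sednet.tensor_decomposition import StackedConnectivityTensor


def _sym_stack(rng, n, t, m):
    """Random stack of symmetric zero-diagonal slices."""
    data = rng.standard_normal((n, n, t, m))
    data = (data + data.transpose(1, 0, 2, 3)) / 2
    idx = np.arange(n)
    data[idx, idx] = 0.0
    return StackedConnectivityTensor(data=data, subject_ids=[f"S{i}" for i in range(m)])


def _tensor(data, sid="S0"):
    return DynamicConnectivityTensor(
        subject_id=sid, data=data, density=0.1, window=WindowSpec(length_trs=5)
    )


def _oracle_basis(data):
    """Explicit mode-1 unfolding SVD (the independent oracle)."""
    unfolding = data.reshape(data.shape[0], -1)
    u, s, _ = np.linalg.svd(unfolding, full_matrices=True)
    return u, s


class TestStacking:
    def test_stack_shape_and_order(self, rng):
        tensors = [_tensor(rng.standard_normal((4, 4, 3)), f"S{i}") for i in range(2)]
        stack = stack_training_tensors(tensors)
        assert stack.data.shape == (4, 4, 3, 2)
        assert stack.subject_ids == ["S0", "S1"]
        np.testing.assert_array_equal(stack.data[:, :, :, 1], tensors[1].data)

    def test_mixed_shapes_rejected(self, rng):
        tensors = [
            _tensor(rng.standard_normal((4, 4, 3))),
            _tensor(rng.standard_normal((4, 4, 5))),
        ]
        with pytest.raises(DimensionError):
            stack_training_tensors(tensors)


class TestBasisFitting:
    def test_matches_explicit_unfolding_svd(self, rng):
        """Gram-matrix eigendecomposition equals the brute-force unfolding SVD."""
        for _ in range(5):
            stack = _sym_stack(rng, 6, 4, 3)
            basis = fit_connectivity_basis(stack, variance_threshold=1.0)
            u_ref, s_ref = _oracle_basis(stack.data)
            np.testing.assert_allclose(basis.singular_values, s_ref[:6], atol=1e-8)
            r = basis.rank
            p_ours = basis.basis @ basis.basis.T
            p_ref = u_ref[:, :r] @ u_ref[:, :r].T
            np.testing.assert_allclose(p_ours, p_ref, atol=1e-8)

    def test_rank_one_stack_recovers_pattern(self, rng):
        u = rng.standard_normal(5)
        u /= np.linalg.norm(u)
        slice_ = np.outer(u, u)
        data = np.repeat(np.repeat(slice_[:, :, None], 3, axis=2)[:, :, :, None], 2, axis=3)
        stack = StackedConnectivityTensor(data=data, subject_ids=["a", "b"])
        basis = fit_connectivity_basis(stack, variance_threshold=0.85)
        assert basis.rank == 1
        assert abs(basis.basis[:, 0] @ u) == pytest.approx(1.0, abs=1e-10)

    def test_variance_capture_minimality(self, rng):
        stack = _sym_stack(rng, 8, 5, 4)
        basis = fit_connectivity_basis(stack, variance_threshold=0.85)
        energy = basis.singular_values**2
        frac = np.cumsum(energy) / energy.sum()
        assert frac[basis.rank - 1] >= 0.85
        if basis.rank > 1:
            assert frac[basis.rank - 2] < 0.85

    def test_orthonormal_columns_and_sign_convention(self, rng):
        stack = _sym_stack(rng, 7, 4, 3)
        basis = fit_connectivity_basis(stack, variance_threshold=0.9)
        np.testing.assert_allclose(
            basis.basis.T @ basis.basis, np.eye(basis.rank), atol=1e-10
        )
        for col in basis.basis.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_all_zero_stack_rejected(self):
        stack = StackedConnectivityTensor(np.zeros((4, 4, 2, 2)), ["a", "b"])
        with pytest.raises(ValidationError):
            fit_connectivity_basis(stack)

    def test_basis_is_pure_function_of_training_stack(self, rng):
        """No-leakage: the basis never depends on subjects outside the stack."""
        stack = _sym_stack(rng, 6, 4, 3)
        before = fit_connectivity_basis(stack, variance_threshold=0.85)
        # anything not in the stack (e.g. a perturbed held-out tensor) is irrelevant
        again = fit_connectivity_basis(stack, variance_threshold=0.85)
        np.testing.assert_array_equal(before.basis, again.basis)


class TestRankSelection:
    @pytest.mark.parametrize(
        "energies,threshold,expected",
        [
            ([1.0, 0.0, 0.0], 0.85, 1),
            ([0.5, 0.2, 0.2, 0.1], 0.85, 3),  # cumulative 0.5, 0.7, 0.9
            ([0.4, 0.3, 0.2, 0.1], 1.0, 4),
            ([0.4, 0.3, 0.3, 0.0], 1.0, 3),  # trailing zero excluded at threshold 1
        ],
    )
    def test_examples(self, energies, threshold, expected):
        sv = np.sqrt(np.array(energies))
        assert select_rank(sv, threshold) == expected

    def test_minimality_against_brute_force(self, rng):
        for _ in range(50):
            sv = np.sort(rng.uniform(0, 1, size=rng.integers(1, 12)))[::-1]
            thr = rng.uniform(0.05, 1.0)
            r = select_rank(sv, thr)
            frac = np.cumsum(sv**2) / np.sum(sv**2)
            candidates = [i + 1 for i in range(len(sv)) if frac[i] >= thr - 1e-15]
            assert r == min(candidates)

    def test_rejects_bad_spectra(self):
        with pytest.raises(ValidationError):
            select_rank(np.zeros(3), 0.85)
        with pytest.raises(ValidationError):
            select_rank(np.array([1.0, 2.0]), 0.85)


class TestProjection:
    def test_identity_basis_is_lossless(self, rng):
        stack = _sym_stack(rng, 5, 3, 2)
        tensor = _tensor(stack.data[:, :, :, 0])
        basis = fit_connectivity_basis(
            StackedConnectivityTensor(stack.data, stack.subject_ids), rank=5
        )
        reduced = project_subject(tensor, basis)
        # R = N: projecting then reconstructing recovers every slice
        u = basis.basis
        for t in range(3):
            np.testing.assert_allclose(
                u @ reduced[:, :, t] @ u.T, tensor.data[:, :, t], atol=1e-10
            )

    def test_single_component_slice_concentrates(self, rng):
        u = np.zeros(4)
        u[0] = 1.0
        data = np.repeat(np.outer(u, u)[:, :, None], 2, axis=2)
        sv = np.array([1.0, 0, 0, 0])
        from sednet.tensor_decomposition import ConnectivityBasis

        basis = ConnectivityBasis(
            basis=np.eye(4)[:, :1],
            singular_values=sv,
            variance_fractions=np.array([1.0, 1, 1, 1]),
            rank=1,
            training_ids=[],
        )
        reduced = project_subject(_tensor(data), basis)
        np.testing.assert_allclose(reduced[0, 0], 1.0)

    def test_projection_never_increases_frobenius_norm(self, rng):
        stack = _sym_stack(rng, 6, 4, 2)
        tensor = _tensor(stack.data[:, :, :, 0])
        basis = fit_connectivity_basis(stack, variance_threshold=0.5)
        reduced = project_subject(tensor, basis)
        for t in range(4):
            assert np.linalg.norm(reduced[:, :, t]) <= np.linalg.norm(
                tensor.data[:, :, t]
            ) + 1e-12


class TestTimeAveraging:
    def test_single_slice_identity(self, rng):
        s = rng.standard_normal((3, 3))
        s = (s + s.T) / 2
        feats = time_average_features(s[:, :, None], "x")
        np.testing.assert_array_equal(feats.reduced, s)

    def test_opposite_slices_cancel(self, rng):
        s = rng.standard_normal((3, 3))
        feats = time_average_features(np.stack([s, -s], axis=2), "x")
        np.testing.assert_allclose(feats.reduced, 0.0, atol=1e-15)

    def test_feature_length_is_rank_squared(self, rng):
        reduced = rng.standard_normal((17, 17, 4))
        feats = time_average_features(reduced, "x")
        assert feats.features.shape == (289,)
        # row-major flattening
        np.testing.assert_array_equal(feats.features, feats.reduced.ravel(order="C"))


class TestComponents:
    def _basis(self, rng, n=10, rank=4):
        stack = _sym_stack(rng, n, 4, 3)
        return fit_connectivity_basis(stack, rank=rank)

    def test_reconstruction_is_rank_one_unit_trace(self, rng):
        basis = self._basis(rng)
        comp = reconstruct_component(basis, 2)
        assert np.linalg.matrix_rank(comp.edge_matrix) == 1
        assert np.trace(comp.edge_matrix) == pytest.approx(1.0)
        np.testing.assert_allclose(
            comp.edge_matrix, np.outer(comp.loading, comp.loading)
        )

    def test_sign_flip_gives_identical_edge_matrix(self, rng):
        basis = self._basis(rng)
        flipped = reconstruct_component(basis, 1)
        loading = -flipped.loading
        np.testing.assert_allclose(
            np.outer(loading, loading), flipped.edge_matrix, atol=1e-15
        )

    def test_index_out_of_range(self, rng):
        basis = self._basis(rng, rank=3)
        with pytest.raises(ConfigurationError):
            reconstruct_component(basis, 4)

    def test_averaging_aligns_signs(self, rng):
        basis = self._basis(rng)
        import copy

        flipped = copy.deepcopy(basis)
        flipped.basis = -flipped.basis
        comp = average_components_across_splits([basis, flipped], 1)
        assert abs(comp.loading @ basis.basis[:, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_averaging_identical_bases_is_identity(self, rng):
        basis = self._basis(rng)
        comp = average_components_across_splits([basis] * 100, 2)
        np.testing.assert_allclose(comp.loading, basis.basis[:, 1], atol=1e-12)

    def test_averaging_noisy_loadings_denoises(self, rng):
        """Averaging sign-aligned noisy copies gets closer to the clean vector."""
        from sednet.tensor_decomposition import ConnectivityBasis

        u = rng.standard_normal(20)
        u /= np.linalg.norm(u)
        bases = []
        cosines = []
        for i in range(50):
            noisy = u + 0.5 * rng.standard_normal(20)
            noisy /= np.linalg.norm(noisy)
            sign = rng.choice([-1.0, 1.0])
            cosines.append(abs(noisy @ u))
            bases.append(
                ConnectivityBasis(
                    basis=(sign * noisy)[:, None],
                    singular_values=np.ones(20),
                    variance_fractions=np.linspace(0.05, 1, 20),
                    rank=1,
                    training_ids=[],
                )
            )
        comp = average_components_across_splits(bases, 1)
        assert abs(comp.loading @ u) > np.mean(cosines)

    def test_top_edge_counts_and_degrees(self, rng):
        basis = self._basis(rng, n=268, rank=2)
        comp = threshold_component_edges(reconstruct_component(basis, 1), 0.01)
        assert len(comp.top_edges) == 358  # round(0.01 * 268*267/2)
        assert comp.node_degrees.sum() == 2 * 358

    def test_star_loading_yields_hub(self):
        from sednet.tensor_decomposition import ComponentMap

        loading = np.array([0.9, 0.2, 0.2, 0.2, 0.2, 0.2])
        loading /= np.linalg.norm(loading)
        comp = ComponentMap(
            index=1,
            loading=loading,
            edge_matrix=np.outer(loading, loading),
            normalized_variance=1.0,
        )
        out = threshold_component_edges(comp, 5 / 15)
        # the five strongest edges are exactly the spokes of region 1
        assert out.node_degrees[0] == 5
        assert all(i == 1 for i, _, _ in out.top_edges)


class TestNormalizedVariance:
    def test_ratio_to_leading_component(self, rng):
        basis = fit_connectivity_basis(_sym_stack(rng, 6, 3, 2), rank=6)
        nv = normalized_variances(basis)
        assert nv[0] == 1.0
        assert (np.diff(nv) <= 1e-12).all()
        np.testing.assert_allclose(
            nv, (basis.singular_values / basis.singular_values[0]) ** 2
        )

    def test_two_to_one_singular_values(self):
        from sednet.tensor_decomposition import ConnectivityBasis

        basis = ConnectivityBasis(
            basis=np.eye(2),
            singular_values=np.array([2.0, 1.0]),
            variance_fractions=np.array([0.8, 1.0]),
            rank=2,
            training_ids=[],
        )
        np.testing.assert_allclose(normalized_variances(basis), [1.0, 0.25])

    def test_planted_four_to_one_energy_ratio(self):
        # slices 2*u1u1' + u2u2' with orthonormal u1,u2 -> Gram eigenvalues 4:1
        u1 = np.array([1.0, 0, 0, 0])
        u2 = np.array([0, 1.0, 0, 0])
        slice_ = 2 * np.outer(u1, u1) + np.outer(u2, u2)
        data = np.repeat(np.repeat(slice_[:, :, None], 5, axis=2)[:, :, :, None], 3, 3)
        stack = StackedConnectivityTensor(data, ["a", "b", "c"])
        basis = fit_connectivity_basis(stack, rank=2)
        nv = normalized_variances(basis)
        assert nv[1] == pytest.approx(0.25, abs=1e-12)
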