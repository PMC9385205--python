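"""Graph Laplacian eigenmodes, expression coefficients, and modulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dynfc as d
from dynfc.eigenmodes import normalized_laplacian_of_frame


class TestGraphLaplacian:
    def test_two_node_normalization_cancels_weight(self):
        for w in (0.5, 1.0, 7.0):
            sc = d.StructuralConnectome(np.array([[0.0, w], [w, 0.0]]), ["a", "b"])
            q = d.graph_laplacian(sc)
            assert np.allclose(q, [[1.0, -1.0], [-1.0, 1.0]])

    def test_k3_spectrum(self):
        w = np.ones((3, 3)) - np.eye(3)
        sc = d.StructuralConnectome(w, ["a", "b", "c"])
        lam = np.linalg.eigvalsh(d.graph_laplacian(sc))
        assert np.allclose(np.sort(lam), [0.0, 1.5, 1.5])

    def test_null_vector_is_sqrt_strength(self, small_connectome):
        q = d.graph_laplacian(small_connectome)
        lam, u = np.linalg.eigh(q)
        assert abs(lam[0]) < 1e-10
        expected = np.sqrt(small_connectome.strengths())
        expected /= np.linalg.norm(expected)
        assert np.allclose(np.abs(u[:, 0]), expected, atol=1e-8)

    def test_isolated_node_named(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        sc = d.StructuralConnectome(w, ["a", "b", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            d.graph_laplacian(sc)


class TestBasis:
    def test_reconstruction_identity(self, small_connectome):
        q = d.graph_laplacian(small_connectome)
        basis = d.eigenmode_basis(q)
        recon = basis.eigenvectors @ np.diag(basis.eigenvalues) @ basis.eigenvectors.T
        assert np.abs(recon - q).max() < 1e-8

    def test_dominant_split_half(self):
        assert d.dominant_indices(214).size == 107
        assert d.non_dominant_indices(214).size == 107
        # odd count: middle mode goes to the dominant set, split stays disjoint
        assert d.dominant_indices(5).size == 3
        assert set(d.dominant_indices(5)) | set(d.non_dominant_indices(5)) == set(range(5))

    def test_node_permutation_consistency(self, small_connectome):
        rng = np.random.default_rng(3)
        perm = rng.permutation(small_connectome.n_rois)
        sc_p = d.StructuralConnectome(small_connectome.weights[np.ix_(perm, perm)],
                                      [small_connectome.roi_labels[i] for i in perm])
        b1 = d.eigenmode_basis(d.graph_laplacian(small_connectome))
        b2 = d.eigenmode_basis(d.graph_laplacian(sc_p))
        assert np.allclose(b1.eigenvalues, b2.eigenvalues, atol=1e-10)
        # compare projectors (eigenvectors of close eigenvalues can rotate)
        for idx in (0, small_connectome.n_rois - 1):
            v1, v2 = b1.eigenvectors[:, idx], b2.eigenvectors[:, idx]
            assert np.isclose(abs(v1[perm] @ v2), 1.0, atol=1e-8)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            d.eigenmode_basis(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestExpression:
    def test_structural_frame_recovers_eigenvalues(self, small_connectome):
        scaled = small_connectome.weights / small_connectome.weights.max()
        sc = d.StructuralConnectome(scaled, small_connectome.roi_labels)
        basis = d.eigenmode_basis(d.graph_laplacian(sc))
        coeffs = d.eigenmode_expression(scaled, basis)
        assert np.allclose(np.sort(coeffs), basis.eigenvalues, atol=1e-8)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_trace_identity_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        frame = rng.uniform(0.05, 1.0, (n, n))
        frame = 0.5 * (frame + frame.T)
        np.fill_diagonal(frame, 0.0)
        sc = d.StructuralConnectome(frame.copy(), [f"r{i}" for i in range(n)])
        basis = d.eigenmode_basis(d.graph_laplacian(sc))
        rng2 = np.random.default_rng(seed + 1)
        other = rng2.uniform(0.05, 1.0, (n, n))
        other = 0.5 * (other + other.T)
        np.fill_diagonal(other, 0.0)
        coeffs = d.eigenmode_expression(other, basis)
        assert np.isclose(coeffs.sum(), np.trace(normalized_laplacian_of_frame(other)),
                          atol=1e-8)

    def test_planted_coefficients_recovered(self, small_connectome):
        tensor, planted, basis, _ = d.generate_eigenmode_fc_series(
            small_connectome, d.PlantedExpressionSpec(n_samples=20, seed=2))
        for t in range(tensor.n_frames):
            coeffs = d.eigenmode_expression(tensor.frames[:, :, t], basis)
            assert np.corrcoef(coeffs, planted[:, t])[0, 1] >= 0.99


class TestPrediction:
    def test_own_basis_exact_reconstruction(self):
        rng = np.random.default_rng(4)
        n = 10
        frame = rng.uniform(0.1, 1.0, (n, n))
        frame = 0.5 * (frame + frame.T)
        np.fill_diagonal(frame, 0.0)
        own_basis = d.eigenmode_basis(normalized_laplacian_of_frame(frame))
        coeffs = d.eigenmode_expression(frame, own_basis)
        pred = d.predict_fc(frame, own_basis, coeffs)
        assert np.abs(pred - frame).max() < 1e-8

    def test_zero_coefficients_give_strength_matrix(self, small_connectome):
        frame = small_connectome.weights / small_connectome.weights.max()
        basis = d.eigenmode_basis(d.graph_laplacian(small_connectome))
        pred = d.predict_fc(frame, basis, np.zeros(small_connectome.n_rois))
        assert np.allclose(pred, np.diag(frame.sum(axis=1)))

    def test_structural_closed_loop_fit(self, small_connectome):
        tensor, _, basis, _ = d.generate_eigenmode_fc_series(
            small_connectome, d.PlantedExpressionSpec(n_samples=15, seed=6))
        series = d.expression_series(tensor, basis)
        assert series.mean_fit >= 0.99


class TestGoodnessOfFit:
    def test_perfect_and_negated(self):
        rng = np.random.default_rng(7)
        frame = rng.uniform(0, 1, (6, 6))
        frame = 0.5 * (frame + frame.T)
        rs, mean_r = d.goodness_of_fit(frame, frame)
        assert np.isclose(mean_r, 1.0)
        rs, mean_r = d.goodness_of_fit(frame, 2.0 - frame)
        assert np.isclose(mean_r, -1.0)

    def test_random_frames_uncorrelated(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 1, (50, 50, 1))
        b = rng.uniform(0, 1, (50, 50, 1))
        _, mean_r = d.goodness_of_fit(0.5 * (a + a.transpose(1, 0, 2)),
                                      0.5 * (b + b.transpose(1, 0, 2)))
        assert abs(mean_r) < 0.1

    def test_constant_frame_skipped(self):
        frames = np.zeros((4, 4, 2))
        frames[:, :, 1] = 1 - np.eye(4)
        rng = np.random.default_rng(1)
        pred = rng.uniform(0, 1, (4, 4, 2))
        rs, mean_r = d.goodness_of_fit(frames, 0.5 * (pred + pred.transpose(1, 0, 2)))
        assert np.isnan(rs[0]) and np.isnan(rs[1])  # both inputs constant per frame


class TestModulation:
    def test_constant_coefficients_zero(self):
        raw, norm = d.modulation_strength(np.ones((4, 10)), [0, 1, 2, 3])
        assert raw == 0.0 and norm == 0.0

    def test_two_point_enumeration(self):
        # one mode, coefficients {0, 1}: ordered pairs contribute 0+1+1+0
        raw, norm = d.modulation_strength(np.array([[0.0, 1.0]]), [0])
        assert raw == 2.0
        assert norm == 0.5

    def test_homogeneity(self):
        rng = np.random.default_rng(3)
        coeffs = rng.uniform(0, 1, (5, 12))
        raw1, _ = d.modulation_strength(coeffs, [1, 2])
        raw2, _ = d.modulation_strength(2.0 * coeffs, [1, 2])
        assert np.isclose(raw2, 2.0 * raw1)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 12))
    @settings(max_examples=30, deadline=None)
    def test_matches_pairwise_oracle(self, seed, n_modes, t):
        rng = np.random.default_rng(seed)
        coeffs = rng.uniform(0, 2, (n_modes, t))
        subset = list(range(n_modes))
        raw, norm = d.modulation_strength(coeffs, subset)
        oracle = sum(abs(coeffs[i, a] - coeffs[i, b])
                     for i in subset for a in range(t) for b in range(t))
        assert np.isclose(raw, oracle, rtol=1e-10)
        assert np.isclose(norm, oracle / (t * t * len(subset)), rtol=1e-10)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            d.modulation_strength(np.ones((3, 4)), [])
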