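import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ortho_group
from sklearn.base import clone

import gaitdiff as gd
from gaitdiff.features import (
    TwoDPCA,
    VectorizedPCA,
    feature_distance,
    fit_basis,
    fit_pca_baseline,
    project,
    reconstruct,
    scatter_trace,
)
from conftest import random_template_stack
from oracles import feature_distance_ref, reconstruct_ref, twodpca_eig, flat_pca_eig


class TestFitBasis:
    def test_identical_templates_zero_scatter(self):
        t = np.random.default_rng(0).random((5, 4))
        basis = fit_basis([t, t], d=2)
        assert np.allclose(basis.covariance, 0)
        assert np.allclose(basis.eigenvalues, 0)

    def test_diagonal_covariance_axes(self):
        # two templates whose centered difference has orthogonal columns with
        # squared norms 3 and 1 -> C_t = diag(6, 2), axes are e_1, e_2
        a = np.array([[np.sqrt(3) / 2, 0.0], [0.0, 0.5]])
        basis = fit_basis([a, -a], d=2)
        np.testing.assert_allclose(basis.covariance, np.diag([1.5, 0.5]), atol=1e-12)
        np.testing.assert_allclose(np.abs(basis.components), np.eye(2), atol=1e-12)
        assert basis.eigenvalues[0] > basis.eigenvalues[1]

    def test_matches_dense_eigensolver_oracle(self, rng):
        stack = random_template_stack(rng)
        basis = fit_basis(stack, d=6)
        mean_ref, C_ref, evals_ref, evecs_ref = twodpca_eig(stack)
        np.testing.assert_allclose(basis.mean_template, mean_ref, rtol=1e-10)
        np.testing.assert_allclose(basis.covariance, C_ref, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(basis.eigenvalues, evals_ref, rtol=1e-8, atol=1e-10)
        cos = np.abs(np.sum(basis.components * evecs_ref, axis=0))
        np.testing.assert_allclose(cos, 1.0, atol=1e-8)

    def test_rejects_bad_inputs(self, rng):
        stack = random_template_stack(rng, M=3, m=4, n=5)
        with pytest.raises(ValueError):
            fit_basis(stack, d=6)  # d > n
        with pytest.raises(ValueError):
            fit_basis(stack[:1], d=2)  # single template
        with pytest.raises(ValueError, match="shape"):
            fit_basis([stack[0], stack[1][:, :4]], d=2)

    def test_psd_and_trace_conservation(self, rng):
        stack = random_template_stack(rng, M=12, m=7, n=9)
        basis = fit_basis(stack, d=3)
        assert basis.eigenvalues.min() >= -1e-9 * basis.eigenvalues.max()
        assert np.trace(basis.covariance) == pytest.approx(basis.eigenvalues.sum())

    def test_sign_convention_deterministic(self, rng):
        stack = random_template_stack(rng)
        W = fit_basis(stack, d=4).components
        idx = np.abs(W).argmax(axis=0)
        assert np.all(W[idx, np.arange(W.shape[1])] > 0)


class TestScatterTrace:
    def test_top_eigenvector_attains_largest_eigenvalue(self, rng):
        stack = random_template_stack(rng)
        basis = fit_basis(stack, d=3)
        val = scatter_trace(basis, basis.components[:, 0])
        assert val == pytest.approx(basis.eigenvalues[0])

    def test_zero_covariance_gives_zero(self):
        t = np.random.default_rng(1).random((4, 3))
        basis = fit_basis([t, t], d=1)
        w = np.array([1.0, 0.0, 0.0])
        assert scatter_trace(basis, w) == 0.0

    def test_bounded_by_top_eigenvalue_and_matches_quadratic_form(self, rng):
        stack = random_template_stack(rng)
        basis = fit_basis(stack, d=2)
        w = rng.standard_normal(stack.shape[2])
        w /= np.linalg.norm(w)
        val = scatter_trace(basis, w)
        assert val == pytest.approx(float(w @ basis.covariance @ w))
        assert val <= basis.eigenvalues[0] + 1e-9

    def test_non_unit_vector_rejected(self, rng):
        basis = fit_basis(random_template_stack(rng), d=2)
        with pytest.raises(ValueError, match="unit"):
            scatter_trace(basis, np.ones(basis.covariance.shape[0]))


class TestProject:
    def test_standard_basis_selects_columns(self, rng):
        stack = random_template_stack(rng, M=4, m=5, n=5)
        basis = fit_basis(stack, d=3)
        object.__setattr__(basis, "components", np.eye(5)[:, :3])
        G = rng.random((5, 5))
        np.testing.assert_allclose(project(G, basis), G[:, :3])

    def test_full_orthonormal_preserves_frobenius(self, rng):
        n = 6
        stack = random_template_stack(rng, M=5, m=4, n=n)
        basis = fit_basis(stack, d=n)
        G = rng.random((4, n))
        Y = project(G, basis)
        assert np.linalg.norm(Y) == pytest.approx(np.linalg.norm(G))

    def test_matches_matrix_product_oracle(self, rng):
        W = ortho_group.rvs(5, random_state=3)[:, :3]
        stack = random_template_stack(rng, M=4, m=6, n=5)
        basis = fit_basis(stack, d=3)
        object.__setattr__(basis, "components", W)
        G = rng.random((6, 5))
        np.testing.assert_allclose(project(G, basis), G @ W, rtol=1e-12)

    def test_linearity_on_raw_grids(self, rng):
        stack = random_template_stack(rng)
        basis = fit_basis(stack, d=3)
        est = TwoDPCA(n_components=3).fit(stack)
        Ga, Gb = rng.random((2, 8, 6))
        lhs = est.transform((2.5 * Ga - 1.25 * Gb)[None])[0]
        rhs = 2.5 * est.transform(Ga[None])[0] - 1.25 * est.transform(Gb[None])[0]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        basis = fit_basis(random_template_stack(rng), d=2)
        with pytest.raises(ValueError, match="match"):
            project(rng.random((8, 7)), basis)


class TestFeatureDistance:
    def test_zero_iff_equal(self, rng):
        Y = rng.random((6, 3))
        assert feature_distance(Y, Y) == 0.0
        assert feature_distance(Y, Y + 1e-3) > 0

    def test_three_four_five(self):
        Ya = np.zeros((2, 1))
        Yb = np.array([[3.0], [4.0]])
        assert feature_distance(Ya, Yb) == pytest.approx(5.0)

    def test_matches_columnwise_oracle_and_symmetry(self, rng):
        Ya, Yb = rng.random((2, 7, 4))
        assert feature_distance(Ya, Yb) == pytest.approx(feature_distance_ref(Ya, Yb))
        assert feature_distance(Ya, Yb) == pytest.approx(feature_distance(Yb, Ya))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            feature_distance(rng.random((4, 2)), rng.random((4, 3)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        A, B, C = r.standard_normal((3, 5, 3))
        assert feature_distance(A, C) <= (
            feature_distance(A, B) + feature_distance(B, C) + 1e-12
        )


class TestReconstruct:
    def test_complete_basis_is_identity(self, rng):
        stack = random_template_stack(rng, M=6, m=8, n=6)
        basis = fit_basis(stack, d=6)
        G = stack[0]
        G_hat = reconstruct(project(G, basis), basis)
        assert np.linalg.norm(G_hat - G) < 1e-8

    def test_empty_sum_is_zero(self, rng):
        basis = fit_basis(random_template_stack(rng), d=2)
        out = reconstruct(np.zeros((8, 0)), basis)
        assert out.shape == (8, 6) and not out.any()

    def test_error_nonincreasing_in_d_matches_oracle(self, rng):
        stack = random_template_stack(rng, M=10, m=8, n=6)
        n = 6
        basis = fit_basis(stack, d=n)
        G = stack[3]
        Y = project(G, basis)
        errors = []
        for d in range(1, n + 1):
            rec = reconstruct(Y[:, :d], basis)
            ref = reconstruct_ref(Y[:, :d], basis.components[:, :d])
            np.testing.assert_allclose(rec, ref, rtol=1e-10, atol=1e-12)
            errors.append(np.linalg.norm(rec - G))
        assert all(a >= b - 1e-10 for a, b in zip(errors, errors[1:]))

    def test_subimage_terms_sum_to_reconstruction(self, rng):
        stack = random_template_stack(rng)
        basis = fit_basis(stack, d=4)
        Y = project(stack[1], basis)
        terms = reconstruct(Y, basis, terms=True)
        assert terms.shape == (4, 8, 6)
        np.testing.assert_allclose(terms.sum(axis=0), reconstruct(Y, basis), rtol=1e-12)

    def test_mismatched_features_rejected(self, rng):
        basis = fit_basis(random_template_stack(rng), d=2)
        with pytest.raises(ValueError):
            reconstruct(np.zeros((8, 3)), basis)


class TestVectorizedPCABaseline:
    def test_rank_bound_two_templates(self, rng):
        stack = random_template_stack(rng, M=2)
        mean, evals, _ = flat_pca_eig(stack)
        assert np.sum(evals > evals[0] * 1e-10) <= 1
        with pytest.raises(ValueError, match="rank"):
            fit_pca_baseline(stack, d=2)

    def test_projection_distances_match_flatten_oracle(self, rng):
        stack = random_template_stack(rng, M=10, m=8, n=6)
        est = fit_pca_baseline(stack, d=5)
        F = est.transform(stack)
        mean, evals, evecs = flat_pca_eig(stack)
        F_ref = (stack.reshape(10, -1) - mean) @ evecs[:, :5]
        for i in range(10):
            for j in range(i):
                got = np.linalg.norm(F[i] - F[j])
                ref = np.linalg.norm(F_ref[i] - F_ref[j])
                assert got == pytest.approx(ref, rel=1e-8)

    def test_full_rank_reconstruction_identity(self, rng):
        stack = random_template_stack(rng, M=10, m=4, n=3)
        est = fit_pca_baseline(stack, d=9)  # rank min(M-1, mn) = 9? mn=12, M-1=9
        rec = est.inverse_transform(est.transform(stack))
        np.testing.assert_allclose(rec, stack, atol=1e-8)


class TestEstimatorProtocol:
    def test_get_set_params_and_clone(self):
        est = TwoDPCA(n_components=7)
        assert est.get_params() == {"n_components": 7}
        est2 = clone(est).set_params(n_components=3)
        assert est2.n_components == 3 and est.n_components == 7

    def test_transform_before_fit_raises(self, rng):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            TwoDPCA().transform(random_template_stack(rng))

    def test_pipeline_roundtrip(self, rng):
        stack = random_template_stack(rng, M=8)
        for est in (TwoDPCA(n_components=3), VectorizedPCA(n_components=3)):
            F = est.fit_transform(stack)
            back = est.inverse_transform(F)
            assert back.shape == stack.shape

    def test_eigenvalue_tail_decays_on_correlated_templates(self, rng):
        # spatially correlated templates concentrate scatter in few axes,
        # so 20 components capture nearly all of it
        from scipy.ndimage import gaussian_filter

        stack = np.stack([
            np.clip(0.5 + 3 * gaussian_filter(rng.standard_normal((120, 88)), 4), 0, 1)
            for _ in range(20)
        ])
        basis = fit_basis(stack, d=5)
        total = basis.eigenvalues.sum()
        assert basis.eigenvalues[20:].sum() < 0.05 * total
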