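"""The projection primitive and its PCA / PLS1 / TP / CP criteria."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from netpls.projection import (
    DegenerateComponentError,
    covariate_project_matrix,
    pca,
    pls1,
    project_component,
    target_projection,
)

from conftest import centered


class TestProjectComponent:
    def test_orthogonal_columns_example(self):
        X = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        t, p, X_next = project_component(X, np.array([1.0, 0.0]))
        np.testing.assert_allclose(t, [2, -2, 0, 0])
        np.testing.assert_allclose(p, [1, 0])
        np.testing.assert_allclose(X_next[:, 0], 0, atol=1e-14)

    def test_rank_one_fully_deflates(self, rng):
        u = rng.standard_normal(8)
        v = rng.standard_normal(3)
        X = np.outer(u - u.mean(), v)
        w = v / np.linalg.norm(v)
        _, _, X_next = project_component(X, w)
        np.testing.assert_allclose(X_next, 0, atol=1e-12)

    def test_residual_orthogonal_to_score(self, rng):
        X = centered(rng.standard_normal((6, 4)))
        w = rng.standard_normal(4)
        w /= np.linalg.norm(w)
        t, _, X_next = project_component(X, w)
        np.testing.assert_allclose(X_next.T @ t, 0, atol=1e-10)

    def test_zero_score_is_degenerate(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        with pytest.raises(DegenerateComponentError):
            project_component(X, np.array([0.0, 1.0]))


class TestPCA:
    def test_matches_truncated_svd(self, rng):
        X = centered(rng.standard_normal((50, 10)))
        model = pca(X, 5)
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        np.testing.assert_allclose(model.explained_ss, s[:5] ** 2, rtol=1e-8)
        for a in range(5):
            assert abs(float(model.weights[:, a] @ vt[a])) == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_columns_give_column_variances_sorted(self, rng):
        col_ss = np.array([9.0, 4.0, 1.0, 0.25]) * 50
        Q, _ = np.linalg.qr(centered(rng.standard_normal((200, 4))))
        Xo = Q * np.sqrt(col_ss)  # exactly orthogonal columns
        Xo = Xo - Xo.mean(axis=0)
        model = pca(Xo, 4)
        np.testing.assert_allclose(
            model.explained_ss, np.sort(np.sum(Xo**2, axis=0))[::-1], rtol=1e-8
        )

    def test_equal_eigenvalues_flagged_degenerate(self):
        # X with two exactly equal leading singular values
        X = np.diag([2.0, 2.0, 1.0])
        X = np.vstack([X, -X])  # centered by symmetry
        model = pca(X, 2)
        np.testing.assert_allclose(model.explained_ss, [8.0, 8.0], rtol=1e-8)
        assert model.degenerate_subspace.all()

    def test_invariants_unit_weights_orthogonal_scores(self, rng):
        X = centered(rng.standard_normal((30, 6)))
        model = pca(X, 4)
        np.testing.assert_allclose(
            np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-10
        )
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        norms = np.linalg.norm(model.scores, axis=0)
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_reconstruction_residual_orthogonality(self, rng):
        X = centered(rng.standard_normal((25, 5)))
        model = pca(X, 3)
        resid = X - model.reconstruct()
        np.testing.assert_allclose(resid.T @ model.scores, 0, atol=1e-8)

    def test_component_count_limit(self, rng):
        X = centered(rng.standard_normal((5, 10)))
        with pytest.raises(ValueError, match="exceeds"):
            pca(X, 5)


class TestPLS1:
    def test_single_column_is_simple_regression(self, rng):
        x = centered(rng.standard_normal((20, 1)))
        y = centered(rng.standard_normal(20))
        model = pls1(x, y, 1)
        slope = float(x[:, 0] @ y / (x[:, 0] @ x[:, 0]))
        assert model.b[0] == pytest.approx(slope, rel=1e-12)

    def test_orthonormal_design_gives_xty(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((30, 4)))
        Q = Q - Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)  # re-orthonormalize after centering
        y = centered(rng.standard_normal(30))
        model = pls1(Q, y, 4)
        np.testing.assert_allclose(model.b, Q.T @ y, atol=1e-8)

    def test_full_rank_equals_least_squares(self, rng):
        X = centered(rng.standard_normal((20, 5)))
        y = centered(rng.standard_normal(20))
        model = pls1(X, y, 5)
        b_ls = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(model.b, b_ls, atol=1e-8)

    def test_b_reproduces_fitted_values(self, rng):
        X = centered(rng.standard_normal((25, 6)))
        y = centered(rng.standard_normal(25))
        model = pls1(X, y, 3)
        fitted_from_b = X @ model.b
        fitted_from_scores = model.latent.scores @ model.inner_coefficients
        np.testing.assert_allclose(
            fitted_from_b, fitted_from_scores, atol=1e-8 * np.linalg.norm(y)
        )

    def test_explained_variance_nondecreasing_in_A(self, rng):
        X = centered(rng.standard_normal((40, 6)))
        y = centered(X @ rng.standard_normal(6) + rng.standard_normal(40))
        fractions = [pls1(X, y, a).explained_y_fraction for a in range(1, 7)]
        assert np.all(np.diff(fractions) >= -1e-12)

    def test_early_stop_when_covariance_exhausted(self, rng):
        x = centered(rng.standard_normal((15, 1)))
        X = np.hstack([x, 2 * x])  # rank 1
        y = centered(x[:, 0] + 0 * x[:, 0])
        with pytest.warns(UserWarning, match="exhausted"):
            model = pls1(X, y, 2)
        assert model.n_components == 1

    @pytest.mark.parametrize("a", [1, 3, 5])
    def test_matches_sklearn_regression_vector(self, rng, a):
        """Independent implementation check: scikit-learn's PLS regression
        produces the same coefficient vector for a single outcome."""
        from sklearn.cross_decomposition import PLSRegression

        X = centered(rng.standard_normal((40, 7)))
        y = centered(X @ rng.standard_normal(7) + rng.standard_normal(40))
        model = pls1(X, y, a)
        sk = PLSRegression(n_components=a, scale=False).fit(X, y)
        np.testing.assert_allclose(model.b, sk.coef_.ravel(), atol=1e-10)

    def test_zero_covariance_errors(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 1.0]) - 1.0
        with pytest.raises(ValueError, match="identically zero"):
            pls1(X, y, 1)


class TestTargetProjection:
    def test_single_component_model_unchanged(self, rng):
        X = centered(rng.standard_normal((20, 4)))
        y = centered(rng.standard_normal(20))
        model = pls1(X, y, 1)
        tp = target_projection(model, X)
        t1 = model.latent.scores[:, 0]
        assert abs(np.corrcoef(tp.score, t1)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert tp.explained_y_fraction == pytest.approx(
            model.explained_y_fraction, rel=1e-10
        )

    def test_score_collinear_with_fitted_values(self, rng):
        X = centered(rng.standard_normal((30, 5)))
        y = centered(X @ rng.standard_normal(5) + 0.5 * rng.standard_normal(30))
        model = pls1(X, y, 3)
        tp = target_projection(model, X)
        yhat = X @ model.b
        cos = tp.score @ yhat / (np.linalg.norm(tp.score) * np.linalg.norm(yhat))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_preserves_pls_explained_y_variance(self, rng):
        X = centered(rng.standard_normal((40, 8)))
        y = centered(X @ rng.standard_normal(8) + rng.standard_normal(40))
        for a in (2, 4):
            model = pls1(X, y, a)
            tp = target_projection(model, X)
            assert tp.explained_y_fraction == pytest.approx(
                model.explained_y_fraction, rel=1e-8
            )

    def test_explained_fractions_in_unit_interval(self, rng):
        X = centered(rng.standard_normal((25, 6)))
        y = centered(rng.standard_normal(25))
        tp = target_projection(pls1(X, y, 2), X)
        assert 0.0 <= tp.explained_y_fraction <= 1.0
        assert 0.0 <= tp.explained_X_fraction <= 1.0


class TestCovariateProjection:
    def test_collinear_outcome_zeroed(self):
        M = np.array([[2.0, 1.0], [-2.0, -1.0]])  # columns [y, z], y = 2z
        _, _, out = covariate_project_matrix(M, col=1)
        np.testing.assert_allclose(out[:, 0], 0, atol=1e-12)
        np.testing.assert_allclose(out[:, 1], 0)

    def test_covariate_column_exactly_zero(self, rng):
        M = centered(rng.standard_normal((10, 4)))
        _, _, out = covariate_project_matrix(M, col=2)
        assert np.all(out[:, 2] == 0.0)

    def test_orthogonal_column_unchanged(self, rng):
        z = centered(rng.standard_normal(20))
        x = centered(rng.standard_normal(20))
        x = x - z * (z @ x) / (z @ z)  # exactly orthogonal to z
        M = np.column_stack([x, z])
        _, _, out = covariate_project_matrix(M, col=1)
        np.testing.assert_allclose(out[:, 0], x, atol=1e-12)

    def test_equals_simple_regression_residuals(self, rng):
        M = centered(rng.standard_normal((30, 6)))
        z = M[:, 0]
        _, _, out = covariate_project_matrix(M, col=0)
        for j in range(1, 6):
            expected = M[:, j] - z * (z @ M[:, j]) / (z @ z)
            np.testing.assert_allclose(out[:, j], expected, atol=1e-10)

    def test_uncorrelated_covariates_commute(self, rng):
        n = 40
        z1 = centered(rng.standard_normal(n))
        z2 = centered(rng.standard_normal(n))
        z2 = z2 - z1 * (z1 @ z2) / (z1 @ z1)  # exactly orthogonal
        X = centered(rng.standard_normal((n, 3)))
        M = np.column_stack([z1, z2, X])
        _, _, a = covariate_project_matrix(M, 0)
        _, _, a = covariate_project_matrix(a, 1)
        _, _, b = covariate_project_matrix(M, 1)
        _, _, b = covariate_project_matrix(b, 0)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_projection_on_zeroed_covariate_errors(self, rng):
        M = centered(rng.standard_normal((10, 3)))
        _, _, out = covariate_project_matrix(M, col=0)
        with pytest.raises(DegenerateComponentError):
            covariate_project_matrix(out, col=0)

    def test_projection_on_fresh_copy_is_identity(self, rng):
        M = centered(rng.standard_normal((15, 3)))
        z = M[:, 0].copy()
        _, _, out = covariate_project_matrix(M, col=0)
        again = np.column_stack([z, out[:, 1:]])
        _, _, out2 = covariate_project_matrix(again, col=0)
        np.testing.assert_allclose(out2[:, 1:], out[:, 1:], atol=1e-12)

    def test_sequential_orthogonalized_equals_mlr_residuals(self, rng):
        """Gram-Schmidt covariate scores reproduce joint MLR residuals."""
        n = 50
        Z = centered(rng.standard_normal((n, 3)))
        X = centered(rng.standard_normal((n, 4)))
        # orthogonalize covariates, project sequentially
        Q, _ = np.linalg.qr(Z)
        M = np.column_stack([Q, X])
        for j in range(3):
            _, _, M = covariate_project_matrix(M, col=j)
        resid_seq = M[:, 3:]
        # oracle: residuals of X regressed on Z by least squares
        B = np.linalg.lstsq(Z, X, rcond=None)[0]
        resid_mlr = X - Z @ B
        np.testing.assert_allclose(resid_seq, resid_mlr, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    X=arrays(
        np.float64,
        (12, 4),
        elements=st.floats(-5, 5, allow_nan=False, width=64),
    ),
    jw=st.integers(0, 3),
)
def test_projection_residual_orthogonality_property(X, jw):
    """For any matrix and indicator weight, residuals are orthogonal to the score."""
    X = X - X.mean(axis=0)
    w = np.zeros(4)
    w[jw] = 1.0
    t = X @ w
    if float(t @ t) <= 1e-12 * max(float(np.sum(X**2)), 1e-300):
        return  # degenerate direction, covered by its own error test
    t, p, X_next = project_component(X, w)
    scale = np.linalg.norm(t) * np.linalg.norm(X_next, axis=0).max() + 1e-30
    assert np.all(np.abs(X_next.T @ t) <= 1e-8 * scale + 1e-12)
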