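import numpy as np
import pandas as pd
import pytest

from syntroscan.ordination import CorrelationPCA, fit_pca, project, standardize


def oracle_eig(X):
    """Brute-force oracle: eigendecomposition of the correlation matrix."""
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    corr = Z.T @ Z / (X.shape[0] - 1)
    w, V = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    return np.maximum(w[order], 0.0), V[:, order], Z


def align_signs(A, B):
    """Flip columns of B to match A's signs (eigenvector sign is arbitrary)."""
    flips = np.sign(np.einsum("ij,ij->j", A, B))
    flips[flips == 0] = 1.0
    return B * flips


class TestStandardize:
    def test_closed_form_column(self):
        Z, centers, scales = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(Z[:, 0], [-1, 0, 1])
        assert centers[0] == 2.0 and scales[0] == 1.0

    def test_constant_column_error_names_category(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "Fnr": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="zero variance: Fnr"):
            standardize(df)

    def test_random_matrix_means_and_variances(self, rng):
        X = rng.gamma(2.0, 1.0, size=(20, 6))
        Z, _, _ = standardize(X)
        assert np.all(np.abs(Z.mean(0)) < 1e-10)
        assert np.allclose(Z.var(0, ddof=1), 1.0, atol=1e-10)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            standardize(np.array([[1.0, 2.0]]))


class TestFit:
    def test_rank_one_two_columns(self):
        x = np.array([1.0, 3.0, 4.0, 7.0])
        X = np.column_stack([x, 2 * x + 5])  # perfectly correlated
        model = CorrelationPCA().fit(X)
        assert np.allclose(model.eigenvalues_all_, [2.0, 0.0], atol=1e-12)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("shape", [(8, 5), (12, 3), (30, 10)])
    def test_matches_eigendecomposition_oracle(self, rng, shape):
        X = rng.normal(size=shape) + rng.gamma(1.5, 1.0, size=shape)
        model = CorrelationPCA().fit(X)
        w, V, Z = oracle_eig(X)
        assert np.allclose(model.eigenvalues_all_, w, atol=1e-8)
        V = align_signs(model.loadings_, V)
        assert np.allclose(model.loadings_, V, atol=1e-8)
        assert np.allclose(model.scores_, Z @ V, atol=1e-8)

    def test_reconstruction_of_standardized_matrix(self, rng):
        X = rng.normal(size=(15, 7))
        model = CorrelationPCA().fit(X)
        Z, _, _ = standardize(X)
        assert np.allclose(model.scores_ @ model.loadings_.T, Z, atol=1e-8)

    def test_loadings_orthonormal_and_eigenvalues_sorted(self, rng):
        model = CorrelationPCA().fit(rng.normal(size=(20, 8)))
        L = model.loadings_
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues_all_) <= 1e-12)
        assert model.scree()["cumulative"].iloc[-1] == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal_with_eigenvalue_norms(self, rng):
        X = rng.normal(size=(25, 6))
        model = CorrelationPCA().fit(X)
        G = model.scores_.T @ model.scores_
        expect = np.diag((X.shape[0] - 1) * model.eigenvalues_all_)
        assert np.allclose(G, expect, atol=1e-6)

    def test_affine_rescaling_leaves_scores_unchanged(self, rng):
        X = rng.normal(size=(18, 5))
        a = rng.uniform(0.5, 4.0, size=5)
        b = rng.normal(size=5)
        m1 = CorrelationPCA().fit(X)
        m2 = CorrelationPCA().fit(X * a + b)
        assert np.allclose(m1.scores_, m2.scores_, atol=1e-8)
        assert np.allclose(m1.eigenvalues_all_, m2.eigenvalues_all_, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        model = CorrelationPCA().fit(rng.normal(size=(12, 6)))
        L = model.loadings_
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_matches_sklearn_oracle_up_to_sign(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(20, 7))
        Z, _, _ = standardize(X)
        ref = sk.PCA().fit(Z)
        model = CorrelationPCA().fit(X)
        assert np.allclose(
            model.eigenvalues_all_[: ref.explained_variance_.size],
            ref.explained_variance_,
            atol=1e-8,
        )
        comp = align_signs(model.loadings_.T[: ref.components_.shape[0]],
                           ref.components_)
        assert np.allclose(
            model.loadings_.T[: ref.components_.shape[0]], comp, atol=1e-8
        )


class TestScreeAndCircle:
    def test_scree_arithmetic(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        X = np.column_stack([x, -x, np.array([1.0, -1.0, 1.0, -1.0])])
        model = CorrelationPCA().fit(X)
        tab = model.scree()
        assert np.allclose(tab["proportion"].sum(), 1.0)
        assert np.all(np.diff(tab["proportion"]) <= 1e-12)

    def test_scree_from_known_eigenvalues(self, rng):
        X = rng.normal(size=(10, 4))
        model = CorrelationPCA().fit(X)
        w, _, _ = oracle_eig(X)
        tab = model.scree()
        assert np.allclose(tab["eigenvalue"], w, atol=1e-8)
        assert np.allclose(tab["proportion"], w / w.sum(), atol=1e-8)

    def test_circle_rank_one_is_unit_correlations(self):
        x = np.array([1.0, 3.0, 4.0, 7.0])
        X = np.column_stack([x, 2 * x + 5])
        circle = CorrelationPCA().fit(X).correlation_circle()
        assert np.allclose(np.abs(circle["PC1"]), 1.0, atol=1e-8)
        assert np.allclose(circle["PC2"], 0.0, atol=1e-6)

    def test_circle_points_inside_unit_disk(self, rng):
        X = rng.normal(size=(14, 6))
        model = CorrelationPCA().fit(X)
        coords = np.column_stack(
            [
                model.loadings_[:, k] * np.sqrt(model.eigenvalues_all_[k])
                for k in range(6)
            ]
        )
        assert np.all((coords**2).sum(axis=1) <= 1 + 1e-8)

    def test_circle_equals_empirical_pearson_correlation(self, rng):
        X = rng.normal(size=(30, 5))
        model = CorrelationPCA().fit(X)
        circle = model.correlation_circle((0, 1))
        Z, _, _ = standardize(X)
        for k, col in enumerate(["PC1", "PC2"]):
            for j in range(5):
                r = np.corrcoef(Z[:, j], model.scores_[:, k])[0, 1]
                assert circle[col].iloc[j] == pytest.approx(r, abs=1e-8)

    def test_circle_component_out_of_range(self, rng):
        model = CorrelationPCA().fit(rng.normal(size=(6, 3)))
        with pytest.raises(IndexError):
            model.correlation_circle((0, 9))


class TestProject:
    def test_training_samples_reproduce_scores(self, rng):
        X = rng.normal(size=(10, 4))
        model = fit_pca(X)
        assert np.allclose(project(model, X), model.scores_, atol=1e-10)

    def test_column_mean_row_projects_to_origin(self, rng):
        X = rng.normal(size=(10, 4))
        model = fit_pca(X)
        assert np.allclose(project(model, X.mean(0)), 0.0, atol=1e-10)

    def test_held_out_row_matches_arithmetic_oracle(self, rng):
        X = rng.normal(size=(10, 4))
        model = fit_pca(X)
        row = rng.normal(size=4)
        expect = ((row - model.mean_) / model.scale_) @ model.loadings_
        assert np.allclose(project(model, row), expect, atol=1e-12)

    def test_missing_category_rejected(self, rng):
        model = fit_pca(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="expected 4"):
            project(model, np.zeros(3))


def test_json_round_trip(tmp_path, rng):
    X = rng.normal(size=(12, 5))
    model = fit_pca(X)
    p = tmp_path / "model.json"
    model.to_json(p)
    back = CorrelationPCA.from_json(p)
    assert back.feature_names_in_ == model.feature_names_in_
    assert np.allclose(back.loadings_, model.loadings_)
    assert np.allclose(back.eigenvalues_all_, model.eigenvalues_all_)
    row = rng.normal(size=5)
    assert np.allclose(back.transform(row), model.transform(row))


def test_get_set_params_round_trip():
    model = CorrelationPCA(n_components=3)
    assert model.get_params() == {"n_components": 3}
    model.set_params(n_components=2)
    assert model.n_components == 2
    with pytest.raises(ValueError, match="invalid parameter"):
        model.set_params(bogus=1)
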