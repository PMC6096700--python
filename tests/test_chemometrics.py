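"""PCA, canonical variate analysis and cross-validated classification."""

import numpy as np
import pytest

from aquaspec.chemometrics import (
    classify,
    fit_cva,
    fit_pca,
    kfold_crossvalidate,
)
from aquaspec.errors import (
    ConfigError,
    SingleClassError,
    StratificationError,
)


def covariance_eig_oracle(X):
    """Brute-force eigendecomposition of the sample covariance matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return evals / evals.sum(), evecs[:, order]


class TestPCA:
    def test_rank_deficient_data_reaches_full_variance(self, rng):
        # 3-D affine subspace embedded in 12 dims, comparable variances
        basis = np.linalg.qr(rng.normal(size=(12, 3)))[0]
        scores = rng.normal(size=(40, 3)) * [1.0, 0.9, 0.8]
        X = scores @ basis.T + rng.uniform(size=12)
        model = fit_pca(X, variance_target=0.95)
        assert model.n_components == 3
        assert abs(model.explained_fraction.sum() - 1.0) < 1e-10

    def test_full_reconstruction_of_centred_data(self, rng):
        X = rng.normal(size=(15, 8))
        model = fit_pca(X, n_components=8)
        scores = model.transform(X)
        recon = scores @ model.loadings + model.mean_spectrum
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_explained_fractions_match_covariance_oracle(self, rng):
        X = rng.normal(size=(10, 8))
        model = fit_pca(X, n_components=8)
        fractions, _ = covariance_eig_oracle(X)
        np.testing.assert_allclose(model.explained_fraction, fractions[:8], atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(30, 12))
        model = fit_pca(X, n_components=6)
        gram = model.loadings @ model.loadings.T
        assert np.max(np.abs(gram - np.eye(6))) < 1e-10

    def test_variance_target_validation(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ConfigError):
            fit_pca(X, variance_target=1.5)
        with pytest.raises(ConfigError):
            fit_pca(X)

    def test_component_cap_applies(self, rng):
        X = rng.normal(size=(50, 40))
        model = fit_pca(X, variance_target=0.9999, cap=21)
        assert model.n_components <= 21


class TestCVA:
    def test_two_class_direction_matches_closed_form(self, rng):
        # classes separated along axis 0 with isotropic within-class noise
        a = rng.normal(0, 1.0, size=(100, 2)) + [4.0, 0.0]
        b = rng.normal(0, 1.0, size=(100, 2))
        X = np.vstack([a, b])
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = fit_cva(X, y)
        # closed form: pooled-within-inverse times centroid difference
        mu_diff = a.mean(axis=0) - b.mean(axis=0)
        sw = (a - a.mean(axis=0)).T @ (a - a.mean(axis=0)) + (
            b - b.mean(axis=0)
        ).T @ (b - b.mean(axis=0))
        direction = np.linalg.solve(sw, mu_diff)
        direction /= np.linalg.norm(direction)
        v = model.canonical_vectors[:, 0] / np.linalg.norm(model.canonical_vectors[:, 0])
        assert abs(float(v @ direction)) > 0.999

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(SingleClassError):
            fit_cva(X, ["only"] * 10)

    def test_three_classes_give_two_canonical_vectors(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.repeat(["a", "b", "c"], 10)
        model = fit_cva(X, y)
        assert model.n_cv == 2

    def test_generalized_eigenproblem_residual_small(self, rng):
        X = rng.normal(size=(60, 6))
        X[:20] += [3, 0, 0, 0, 0, 0]
        X[20:40] += [0, 3, 0, 0, 0, 0]
        y = np.repeat(["a", "b", "c"], 20)
        model = fit_cva(X, y)
        from aquaspec.chemometrics import _scatter_matrices

        _, sb, sw, _ = _scatter_matrices(X, np.asarray(y))
        sw_reg = sw + model.ridge * np.eye(6)
        for j in range(model.n_cv):
            v = model.canonical_vectors[:, j]
            lam = model.eigenvalues[j]
            resid = sb @ v - lam * (sw_reg @ v)
            assert np.linalg.norm(resid) / np.linalg.norm(sb @ v) < 1e-8

    def test_eigenvalues_non_negative_and_sorted(self, rng):
        X = rng.normal(size=(45, 4))
        y = np.repeat(["a", "b", "c"], 15)
        model = fit_cva(X, y)
        assert np.all(model.eigenvalues >= 0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_projection_invariant_to_row_order(self, rng):
        X = rng.normal(size=(40, 5))
        X[:20] += 2.0
        y = np.array(["a"] * 20 + ["b"] * 20)
        perm = rng.permutation(40)
        m1 = fit_cva(X, y)
        m2 = fit_cva(X[perm], y[perm])
        np.testing.assert_allclose(
            np.abs(m1.canonical_vectors), np.abs(m2.canonical_vectors), atol=1e-8
        )


class TestClassify:
    def test_centroid_classifies_to_own_class(self, rng):
        X = rng.normal(size=(40, 4))
        X[:20] += 3.0
        y = ["a"] * 20 + ["b"] * 20
        model = fit_cva(X, y)
        centroid_a = X[:20].mean(axis=0)
        label, coords, dist, tie = classify(model, centroid_a)
        assert label == "a"
        assert dist["a"] < 1e-9
        assert not tie

    def test_equidistant_point_breaks_tie_lexicographically(self, rng):
        X = rng.normal(size=(40, 2))
        X[:20, 0] += 4.0
        y = ["beta"] * 20 + ["alpha"] * 20
        model = fit_cva(X, y)
        midpoint = (model.class_centroids["alpha"] + model.class_centroids["beta"]) / 2
        # invert the canonical projection at the midpoint: use a point whose
        # projection is the midpoint by solving least squares
        v = model.canonical_vectors
        x_mid, *_ = np.linalg.lstsq(v.T, midpoint, rcond=None)
        label, _, _, tie = classify(model, x_mid)
        assert label == "alpha"
        assert tie

    def test_perfect_training_accuracy_on_separated_classes(self, rng):
        centers = np.array([[8.0, 0.0, 0.0], [0.0, 8.0, 0.0], [0.0, 0.0, 8.0]])
        X = np.vstack([rng.normal(0, 0.5, size=(100, 3)) + c for c in centers])
        y = np.repeat(["a", "b", "c"], 100)
        model = fit_cva(X, y)
        preds = [classify(model, x)[0] for x in X]
        assert preds == list(y)


class TestKFold:
    def test_each_spectrum_tested_exactly_once(self, rng):
        X = rng.normal(size=(103, 6))
        y = np.array((["a", "b"] * 52)[:103])
        report = kfold_crossvalidate(X, y, k=5, seed=3, n_components=4,
                                     variance_target=None)
        folds = report.fold_assignment["fold"]
        assert set(folds) == {1, 2, 3, 4, 5}
        assert len(folds) == 103
        # stratified: per-class fold test sizes differ by at most one
        for c in ("a", "b"):
            sizes = report.fold_assignment[y == c].groupby("fold").size()
            assert sizes.max() - sizes.min() <= 1

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = ["a"] * 7 + ["b"] * 3
        with pytest.raises(StratificationError):
            kfold_crossvalidate(X, y, k=5)

    def test_null_labels_score_near_chance(self, rng):
        """Coin-flip labels on one distribution: accuracy ~50%, no leakage."""
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 20))
            y = np.array(["a", "b"] * 100)
            rep = kfold_crossvalidate(X, y, k=5, seed=seed, variance_target=0.95,
                                      pc_cap=10)
            accs.append(rep.overall_mean)
        mean_acc = np.mean(accs)
        # central 99% binomial band for 10x200 decisions around 50%
        half_width = 2.576 * np.sqrt(0.25 / 2000) * 100
        assert abs(mean_acc - 50.0) < 3 * half_width

    def test_report_table_has_range_and_mean_rows(self, rng):
        X = rng.normal(size=(60, 5))
        X[:30] += 4.0
        y = np.array(["a"] * 30 + ["b"] * 30)
        report = kfold_crossvalidate(X, y, k=5, seed=0, n_components=3,
                                     variance_target=None)
        table = report.to_table()
        assert "Range (%)" in table.index and "Mean (%)" in table.index
        assert ((report.fold_class_pct.to_numpy() >= 0)
                & (report.fold_class_pct.to_numpy() <= 100)).all()
        np.testing.assert_allclose(
            report.per_class_mean.to_numpy(),
            report.fold_class_pct.mean(axis=0).to_numpy(),
        )
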