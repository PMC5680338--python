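"""Classifier families vs dense linear-algebra oracles and scikit-learn
cross-checks; tie-break and preprocessing-symmetry contracts."""

import numpy as np
import pytest

from meatspec.classifiers import (
    KNearestClassifier,
    LinearDiscriminantClassifier,
    PCADiscriminantClassifier,
    PLSDiscriminantClassifier,
    SIMCAClassifier,
)


def make_blobs(n_per=20, centers=((0, 0, 0), (8, 8, 0), (0, 8, 8)), spread=0.4, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(centers):
        X.append(np.asarray(c) + spread * rng.standard_normal((n_per, len(c))))
        y += [chr(ord("a") + i)] * n_per
    return np.vstack(X), np.array(y)


ALL_MODELS = [
    lambda: LinearDiscriminantClassifier(),
    lambda: PCADiscriminantClassifier(n_pcs=2),
    lambda: PLSDiscriminantClassifier(n_lv=2),
    lambda: KNearestClassifier(k=3),
    lambda: SIMCAClassifier(n_pcs=2),
]


@pytest.mark.parametrize("factory", ALL_MODELS)
def test_every_family_separates_wide_blobs_perfectly(factory):
    X, y = make_blobs()
    model = factory().fit(X, y)
    assert (model.predict(X) == y).all()


@pytest.mark.parametrize("factory", ALL_MODELS)
def test_prediction_rows_are_independent_of_ordering(factory):
    X, y = make_blobs(seed=3)
    rng = np.random.default_rng(1)
    Xnew = X + 0.1 * rng.standard_normal(X.shape)
    model = factory().fit(X, y)
    pred = model.predict(Xnew)
    perm = rng.permutation(len(Xnew))
    assert np.array_equal(model.predict(Xnew[perm]), pred[perm])


class TestLDA:
    def test_three_classes_give_two_canonical_variables(self):
        X, y = make_blobs()
        model = LinearDiscriminantClassifier().fit(X, y)
        assert model.loadings_.shape[1] == 2
        assert model.transform(X).shape == (len(X), 2)

    def test_canonical_directions_match_dense_generalized_eigen_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.random((30, 6))
        y = np.array(["a", "b", "c"] * 10)
        model = LinearDiscriminantClassifier(ridge=1e-9).fit(X, y)

        # oracle: eig of inv(Sw + ridge I) @ Sb assembled by explicit sums
        classes = np.unique(y)
        grand = X.mean(axis=0)
        Sw = np.zeros((6, 6))
        Sb = np.zeros((6, 6))
        for c in classes:
            Xc = X[y == c]
            mc = Xc.mean(axis=0)
            Sw += (Xc - mc).T @ (Xc - mc)
            Sb += len(Xc) * np.outer(mc - grand, mc - grand)
        evals, evecs = np.linalg.eig(np.linalg.inv(Sw + 1e-9 * np.eye(6)) @ Sb)
        order = np.argsort(evals.real)[::-1][:2]
        for k in range(2):
            v_model = model.loadings_[:, k]
            v_oracle = evecs[:, order[k]].real
            cos = abs(v_model @ v_oracle) / (np.linalg.norm(v_model) * np.linalg.norm(v_oracle))
            assert cos == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(np.sort(model.eigenvalues_), np.sort(evals.real[order]), atol=1e-8)

    def test_training_centroid_classifies_to_own_class(self):
        X, y = make_blobs()
        model = LinearDiscriminantClassifier().fit(X, y)
        for c in np.unique(y):
            centroid = X[y == c].mean(axis=0)
            assert model.predict(centroid[None, :])[0] == c

    def test_equidistant_point_breaks_tie_alphabetically(self):
        # mirror-symmetric two-class problem; the origin is exactly between
        X = np.array([[-2.0, 1.0], [-2.0, -1.0], [-3.0, 0.0], [2.0, 1.0], [2.0, -1.0], [3.0, 0.0]])
        y = np.array(["zebra", "zebra", "zebra", "apple", "apple", "apple"])
        model = LinearDiscriminantClassifier().fit(X, y)
        assert model.predict(np.zeros((1, 2)))[0] == "apple"

    def test_agreement_with_quadratic_form_oracle(self):
        rng = np.random.default_rng(11)
        X, y = make_blobs(spread=1.5, seed=5)
        model = LinearDiscriminantClassifier().fit(X, y)
        Xnew = X + 0.5 * rng.standard_normal(X.shape)
        pred = model.predict(Xnew)
        # oracle: recompute distances by explicit quadratic forms
        T = model.transform(Xnew)
        oracle = []
        for t in T:
            best, best_d = None, np.inf
            for k, c in enumerate(model.classes_):
                diff = t - model.centroids_[k]
                d = float(diff @ model.class_cov_inv_[c] @ diff)
                if d < best_d:
                    best, best_d = c, d
            oracle.append(best)
        assert (pred == np.array(oracle)).mean() >= 0.95

    def test_too_many_variables_points_to_wilks_selection(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 20))
        y = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError, match="Wilks"):
            LinearDiscriminantClassifier().fit(X, y)

    def test_sklearn_cross_check_on_separable_data(self):
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = make_blobs(spread=1.0, seed=8)
        ours = LinearDiscriminantClassifier(covariance="pooled").fit(X, y)
        ref = sklearn_lda.LinearDiscriminantAnalysis().fit(X, y)
        rng = np.random.default_rng(2)
        Xnew = X + 0.3 * rng.standard_normal(X.shape)
        assert (ours.predict(Xnew) == ref.predict(Xnew)).mean() >= 0.95


class TestPCADA:
    def test_pca_scores_match_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(3)
        X = rng.random((5, 4))
        y = np.array(["a", "a", "b", "b", "b"])
        model = PCADiscriminantClassifier(n_pcs=2, scaling="none").fit(X, y)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        scores_oracle = Xc @ Vt[:2].T
        scores_model = model.pca_.scores(Xc + X.mean(axis=0))
        for k in range(2):
            assert np.allclose(scores_model[:, k], scores_oracle[:, k], atol=1e-10) or np.allclose(
                scores_model[:, k], -scores_oracle[:, k], atol=1e-10
            )

    def test_minimal_components_still_separate_blobs(self):
        X, y = make_blobs()
        model = PCADiscriminantClassifier(n_pcs=2).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_n_pcs_capped_by_sample_count(self):
        X, y = make_blobs(n_per=3)
        with pytest.raises(ValueError):
            PCADiscriminantClassifier(n_pcs=30).fit(X, y)


class TestPLSDA:
    def test_single_latent_variable_separates_two_classes(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((10, 3)) + [5, 0, 0], rng.standard_normal((10, 3))])
        y = np.array(["hi"] * 10 + ["lo"] * 10)
        model = PLSDiscriminantClassifier(n_lv=1).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_x_scores_are_orthogonal(self):
        rng = np.random.default_rng(5)
        X = rng.random((15, 6))
        y = np.array(["a", "b", "c"] * 5)
        model = PLSDiscriminantClassifier(n_lv=4).fit(X, y)
        G = model.scores_.T @ model.scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_first_weight_is_dominant_singular_direction_of_cross_product(self):
        rng = np.random.default_rng(6)
        X = rng.random((6, 3))
        y = np.array(["a", "a", "b", "b", "c", "c"])
        model = PLSDiscriminantClassifier(n_lv=1).fit(X, y)
        Xc = X - X.mean(axis=0)
        Y = (y[:, None] == np.array(["a", "b", "c"])[None, :]).astype(float)
        Yc = Y - Y.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        # with one LV every coefficient column is proportional to the first
        # NIPALS weight, which converges to the dominant left singular
        # vector of X'Y
        col = model.coef_[:, np.argmax(np.abs(model.coef_).sum(axis=0))]
        cos = abs(col @ U[:, 0]) / np.linalg.norm(col)
        assert cos == pytest.approx(1.0, abs=1e-8)


class TestKNN:
    def test_k1_returns_own_label_on_training_points(self):
        X, y = make_blobs(spread=1.0)
        model = KNearestClassifier(k=1).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_k_equal_n_with_uniform_labels(self):
        rng = np.random.default_rng(8)
        X = rng.random((12, 3))
        y = np.array(["only"] * 12)
        model = KNearestClassifier(k=12).fit(X, y)
        assert (model.predict(rng.random((5, 3))) == "only").all()

    def test_k3_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.random((20, 4))
        y = np.array(list("abcd") * 5)
        model = KNearestClassifier(k=3).fit(X, y)
        Xnew = rng.random((15, 4))
        pred = model.predict(Xnew)
        for i, x in enumerate(Xnew):
            d = np.sqrt(((X - x) ** 2).sum(axis=1))
            nn = np.argsort(d, kind="stable")[:3]
            votes = {}
            dists = {}
            for j in nn:
                votes[y[j]] = votes.get(y[j], 0) + 1
                dists.setdefault(y[j], []).append(d[j])
            best = sorted(votes, key=lambda c: (-votes[c], np.mean(dists[c]), c))[0]
            assert pred[i] == best

    def test_mahalanobis_metric_accepted(self):
        X, y = make_blobs(spread=0.5)
        model = KNearestClassifier(k=3, metric="mahalanobis").fit(X, y)
        assert (model.predict(X) == y).all()


class TestSIMCA:
    def test_class_mean_is_assigned_with_near_zero_residual(self):
        X, y = make_blobs(n_per=15, spread=0.5, seed=10)
        model = SIMCAClassifier(n_pcs=2).fit(X, y)
        for c in np.unique(y):
            mean = X[y == c].mean(axis=0)[None, :]
            assert model.predict(mean)[0] == c

    def test_per_class_component_counts_accepted(self):
        X, y = make_blobs(n_per=15, seed=12)
        model = SIMCAClassifier(n_pcs={"a": 2, "b": 1, "c": 2}).fit(X, y)
        assert model.models_["b"].n_pcs == 1
        assert (model.predict(X) == y).all()

    def test_class_residuals_match_full_reconstruction_oracle(self):
        rng = np.random.default_rng(13)
        Xc = rng.random((6, 4))
        y = np.array(["z"] * 6 + ["w"] * 6)
        X = np.vstack([Xc, Xc + 5.0])
        model = SIMCAClassifier(n_pcs=2, scaling="none").fit(X, y)
        m = model.models_["z"]
        E = Xc - Xc.mean(axis=0)
        U, s, Vt = np.linalg.svd(E, full_matrices=False)
        recon = U[:, :2] @ np.diag(s[:2]) @ Vt[:2]
        q_oracle = ((E - recon) ** 2).sum(axis=1)
        T = E @ m.loadings
        q_model = ((E - T @ m.loadings.T) ** 2).sum(axis=1)
        assert np.allclose(q_model, q_oracle, atol=1e-8)

    def test_accept_matrix_accepts_own_calibration_majority(self):
        X, y = make_blobs(n_per=20, seed=14)
        model = SIMCAClassifier(n_pcs=2).fit(X, y)
        acc = model.accepts(X)
        for k, c in enumerate(model.classes_):
            assert acc[y == c, k].mean() > 0.9

    def test_component_count_must_be_below_class_size(self):
        X, y = make_blobs(n_per=4)
        with pytest.raises(ValueError, match="class size"):
            SIMCAClassifier(n_pcs=5).fit(X, y)
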