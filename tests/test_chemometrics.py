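import logging

import numpy as np
import pytest

from mbfuse.chemometrics import (Autoscaler, PLSModel, autoscale,
                                 classification_metrics, load_model, pca,
                                 plsda_fit, plsda_predict, save_model, vip)


# ---------------------------------------------------------------------------
# autoscaling
# ---------------------------------------------------------------------------

class TestAutoscale:
    def test_unit_variance_example(self):
        Xs, centers, scales = autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Xs.ravel(), [-1, 0, 1])
        assert centers[0] == 2.0 and scales[0] == 1.0

    def test_columns_standardized(self, rng):
        Xs, _, _ = autoscale(rng.normal(5, 3, size=(20, 4)))
        np.testing.assert_allclose(Xs.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_stored_transform_reproduces_training_scaling(self, rng):
        X = rng.normal(size=(15, 3))
        scaler = Autoscaler().fit(X)
        np.testing.assert_allclose(scaler.transform(X), autoscale(X)[0])

    def test_out_of_sample_uses_training_parameters(self, rng):
        X = rng.normal(size=(15, 3))
        scaler = Autoscaler().fit(X)
        row = np.array([[100.0, 100.0, 100.0]])
        expected = (row - scaler.centers) / scaler.scales
        np.testing.assert_allclose(scaler.transform(row), expected)

    def test_constant_column_neutralized_with_warning(self, caplog):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with caplog.at_level(logging.WARNING):
            Xs, _, scales = autoscale(X)
        np.testing.assert_allclose(Xs[:, 1], 0.0)
        assert scales[1] == 1.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            autoscale(np.full((4, 2), 7.0))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_rank_one_data_has_unit_first_fraction(self):
        x = np.array([1.0, 2, 3, 4])
        Xs, _, _ = autoscale(np.column_stack([x, 2 * x]))
        model = pca(Xs, k=1)
        assert model.variance_fractions[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        Xs, _, _ = autoscale(rng.normal(size=(10, 4)))
        model = pca(Xs)
        np.testing.assert_allclose(model.scores @ model.loadings.T, Xs,
                                   atol=1e-8)

    def test_fractions_match_correlation_eigenvalues(self, rng):
        X = rng.normal(size=(5, 3))
        Xs, _, _ = autoscale(X)
        model = pca(Xs, k=3)
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(model.variance_fractions, eig / eig.sum(),
                                   atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        Xs, _, _ = autoscale(rng.normal(size=(12, 5)))
        model = pca(Xs, k=4)
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(4), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        Xs, _, _ = autoscale(rng.normal(size=(12, 5)))
        m1, m2 = pca(Xs, k=3), pca(Xs, k=3)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        for j in range(3):
            i = np.argmax(np.abs(m1.loadings[:, j]))
            assert m1.loadings[i, j] > 0


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def separable_toy(rng, n=20, p=5):
    labels = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    y = (labels == "pos").astype(float)
    X = rng.normal(size=(n, p))
    X[:, 0] = y  # the dummy itself is a feature
    return X, labels


class TestPLSDA:
    def test_separable_training_accuracy_is_perfect(self, rng):
        X, labels = separable_toy(rng)
        model = plsda_fit(X, labels, n_components=1)
        pred, _ = plsda_predict(model, X)
        assert (pred == labels).all()

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 10))
        labels = np.repeat(["a", "b"], 15)
        model = plsda_fit(X, labels, n_components=4)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_full_rank_limit_equals_least_squares(self, rng):
        X = rng.normal(size=(8, 3))
        labels = np.array(["a", "b"] * 4)
        model = plsda_fit(X, labels, n_components=3, scale=False)
        _, yhat = plsda_predict(model, X)
        y = (labels == "b").astype(float)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(yhat, Xc @ beta + y.mean(), atol=1e-8)

    def test_threshold_tie_goes_to_positive_class(self):
        model = PLSModel(classes=("neg", "pos"),
                         weights=np.array([[1.0]]), x_loadings=np.array([[1.0]]),
                         y_loadings=np.array([0.0]), scores=np.zeros((2, 1)),
                         ssy=np.array([1.0]), y_mean=0.5, scaler=None)
        pred, yhat = plsda_predict(model, np.array([[3.0]]))
        assert yhat[0] == 0.5 and pred[0] == "pos"

    def test_feature_permutation_invariance(self, rng):
        X = rng.normal(size=(20, 6))
        labels = np.repeat(["a", "b"], 10)
        perm = rng.permutation(6)
        m1 = plsda_fit(X, labels, n_components=2)
        m2 = plsda_fit(X[:, perm], labels, n_components=2)
        _, y1 = plsda_predict(m1, X)
        _, y2 = plsda_predict(m2, X[:, perm])
        np.testing.assert_allclose(y1, y2, atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        labels = np.array(["a", "b"] * 3)
        with pytest.raises(ValueError, match="rank"):
            plsda_fit(X, labels, n_components=5)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            plsda_fit(rng.normal(size=(6, 2)), np.array(["a"] * 6), 1)

    def test_json_round_trip_reproduces_predictions(self, rng, tmp_path):
        X = rng.normal(size=(20, 6))
        labels = np.repeat(["a", "b"], 10)
        model = plsda_fit(X, labels, n_components=2)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        X_new = rng.normal(size=(5, 6))
        np.testing.assert_allclose(plsda_predict(back, X_new)[1],
                                   plsda_predict(model, X_new)[1], atol=1e-12)
        assert back.classes == model.classes

    def test_agrees_with_reference_pls_regression(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(25, 8))
        labels = np.repeat(["a", "b"], [12, 13])
        y = (labels == "b").astype(float)
        model = plsda_fit(X, labels, n_components=3, scale=False)
        _, ours = plsda_predict(model, X)
        ref = sklearn.PLSRegression(n_components=3, scale=False)
        ref.fit(X, y)
        np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

class TestVIP:
    def test_uniform_weights_give_unit_vips(self):
        # all feature columns identical => equal weights at A=1
        y = np.array([0.0, 0, 1, 1, 0, 1])
        X = np.column_stack([y + 0.01 * np.arange(6)] * 4)
        model = plsda_fit(X, np.where(y > 0, "b", "a"), n_components=1)
        np.testing.assert_allclose(vip(model), 1.0, atol=1e-10)

    def test_sum_of_squares_identity(self, rng):
        for _ in range(10):
            n, p = 20, int(rng.integers(3, 12))
            X = rng.normal(size=(n, p))
            labels = np.repeat(["a", "b"], n // 2)
            a = int(rng.integers(1, 4))
            model = plsda_fit(X, labels, n_components=a)
            v = vip(model)
            assert (v ** 2).sum() == pytest.approx(p, abs=1e-8 * p)

    def test_single_informative_feature_attains_max_vip(self, rng):
        X = rng.normal(size=(40, 10))
        labels = np.repeat(["a", "b"], 20)
        X[:, 3] += 5 * (labels == "b")
        model = plsda_fit(X, labels, n_components=2)
        assert np.argmax(vip(model)) == 3


# ---------------------------------------------------------------------------
# figures of merit
# ---------------------------------------------------------------------------

class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = ["p", "p", "n", "n"]
        fom = classification_metrics(y, y, "p")
        assert (fom.accuracy, fom.sensitivity, fom.specificity) == (100, 100, 100)

    def test_confusion_count_arithmetic(self):
        y_true = ["p"] * 4 + ["n"] * 6
        y_pred = ["p", "p", "p", "n", "p", "p", "n", "n", "n", "n"]
        fom = classification_metrics(y_true, y_pred, "p")
        assert fom.sensitivity == pytest.approx(75.0)
        assert fom.specificity == pytest.approx(100 * 4 / 6)
        assert fom.accuracy == pytest.approx(70.0)

    def test_swapping_positive_class_swaps_sens_spec(self):
        y_true = ["p"] * 4 + ["n"] * 6
        y_pred = ["p", "p", "p", "n", "p", "p", "n", "n", "n", "n"]
        a = classification_metrics(y_true, y_pred, "p")
        b = classification_metrics(y_true, y_pred, "n")
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            classification_metrics(["p", "p"], ["p", "n"], "p")
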