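import numpy as np
import pytest

from nirfish.plsda import (
    PLSDAModel,
    classification_metrics,
    coefficients,
    fit_plsda,
    predict,
    vip_scores,
)


def _random_instance(rng, n=None, p=None, scale=True):
    n = n or rng.integers(8, 21)
    p = p or rng.integers(2, 9)
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 0.5).astype(int)
    while np.unique(y).size < 2:
        y = (rng.random(n) < 0.5).astype(int)
    return X, y


def _ols_fitted(X, y):
    """Independent oracle: multiple linear regression with intercept."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return Z @ beta


class TestFit:
    def test_univariate_equals_ols_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = np.array([0, 1] * 6)
        model = fit_plsda(x[:, None], y, 1, autoscale=False)
        xc = x - x.mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        b, intercept = coefficients(model)
        np.testing.assert_allclose(b[0], slope, atol=1e-12)
        np.testing.assert_allclose(intercept, y.mean() - 0.0, atol=1e-12)
        np.testing.assert_allclose(model.fitted_response, y.mean() + xc * slope, atol=1e-12)

    def test_full_component_fit_equals_ols(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            X, y = _random_instance(rng)
            n, p = X.shape
            A = min(n - 1, p)
            model = fit_plsda(X, y, A, autoscale=True)
            np.testing.assert_allclose(model.fitted_response, _ols_fitted(X, y), atol=1e-8)

    def test_matches_sklearn_pls_regression(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(2)
        for _ in range(10):
            X, y = _random_instance(rng)
            A = 2
            model = fit_plsda(X, y, A, autoscale=True)
            ref = sklearn_pls.PLSRegression(n_components=A, scale=True).fit(X, y.astype(float))
            np.testing.assert_allclose(
                model.fitted_response, ref.predict(X).ravel(), atol=1e-8
            )

    def test_score_orthogonality_and_coef_collapse(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X, y = _random_instance(rng)
            A = min(3, min(X.shape[0] - 1, X.shape[1]))
            model = fit_plsda(X, y, A, autoscale=True)
            G = model.scores.T @ model.scores
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max() < 1e-8
            # prediction through (W, P, q) component-wise equals collapsed b
            y_hat, _ = predict(model, X)
            via_scores = model.intercept + model.scores @ model.y_loadings
            np.testing.assert_allclose(y_hat, via_scores, atol=1e-10)

    def test_errors(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_plsda(X, np.zeros(6), 1)
        with pytest.raises(ValueError, match="n_components"):
            fit_plsda(X, np.array([0, 1, 0, 1, 0, 1]), 6)
        with pytest.raises(ValueError, match="rows"):
            fit_plsda(X, np.array([0, 1]), 1)


class TestPredict:
    def test_training_set_reproduces_fitted_values(self):
        rng = np.random.default_rng(4)
        X, y = _random_instance(rng)
        model = fit_plsda(X, y, 2, autoscale=True)
        y_hat, _ = predict(model, X)
        np.testing.assert_allclose(y_hat, model.fitted_response, atol=1e-12)

    def test_threshold_tie_goes_to_treated(self):
        rng = np.random.default_rng(5)
        X, y = _random_instance(rng)
        model = fit_plsda(X, y, 1, autoscale=True)
        model.coef[:] = 0.0
        model.intercept = model.threshold  # response exactly at threshold
        _, classes = predict(model, X)
        assert np.all(classes == 1)

    def test_joint_column_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X, y = _random_instance(rng, n=14, p=6)
        model = fit_plsda(X, y, 2, autoscale=True)
        perm = rng.permutation(6)
        model_p = fit_plsda(X[:, perm], y, 2, autoscale=True)
        y_a, _ = predict(model, X)
        y_b, _ = predict(model_p, X[:, perm])
        np.testing.assert_allclose(y_a, y_b, atol=1e-10)

    def test_column_count_mismatch(self):
        rng = np.random.default_rng(7)
        X, y = _random_instance(rng, n=10, p=4)
        model = fit_plsda(X, y, 1)
        with pytest.raises(ValueError, match="columns"):
            predict(model, X[:, :3])

    def test_separable_classes_classify_perfectly(self):
        x = np.concatenate([np.linspace(-3, -1, 8), np.linspace(1, 3, 8)])
        y = np.array([0] * 8 + [1] * 8)
        model = fit_plsda(x[:, None], y, 1)
        _, classes = predict(model, x[:, None])
        assert classification_metrics(y, classes).accuracy == 100.0


class TestVIP:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            X, y = _random_instance(rng)
            A = min(3, min(X.shape[0] - 1, X.shape[1]))
            model = fit_plsda(X, y, A, autoscale=True)
            v = vip_scores(model)
            assert np.all(v >= 0)
            np.testing.assert_allclose(np.mean(v**2), 1.0, atol=1e-10)

    def test_single_informative_variable_concentrates_sqrt_p(self):
        # one predictive column among pure noise: w ~ e1, VIP1 -> sqrt(p)
        rng = np.random.default_rng(9)
        p = 9
        y = np.array([0, 1] * 12)
        X = 1e-8 * rng.normal(size=(24, p))
        X[:, 0] = y - 0.5
        model = fit_plsda(X, y, 1, autoscale=False)
        v = vip_scores(model)
        np.testing.assert_allclose(v[0], np.sqrt(p), rtol=1e-5)
        assert np.all(v[1:] < 1e-3)

    def test_equal_weights_give_unit_vip(self):
        y = np.array([0, 1] * 10)
        X = np.tile((y - 0.5)[:, None], (1, 4)) + 0.0
        model = fit_plsda(X, y, 1, autoscale=False)
        np.testing.assert_allclose(vip_scores(model), 1.0, atol=1e-10)


class TestMetrics:
    def test_perfect_and_degenerate_confusions(self):
        y = np.array([0] * 18 + [1] * 18)
        m = classification_metrics(y, y)
        assert m.accuracy == 100.0 and m.ner == 100.0
        all_one = classification_metrics(y, np.ones_like(y))
        assert all_one.accuracy == 50.0 and all_one.ner == 50.0

    def test_single_error_in_balanced_36(self):
        y = np.array([0] * 18 + [1] * 18)
        pred = y.copy()
        pred[0] = 1
        m = classification_metrics(y, pred)
        assert round(m.accuracy, 2) == 97.22
        assert round(m.ner, 2) == 97.22
        np.testing.assert_array_equal(m.confusion, [[17, 1], [0, 18]])

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            classification_metrics([0, 1], [0])
        with pytest.raises(ValueError, match="labels"):
            classification_metrics([0, 2], [0, 1])


def test_model_serialization_roundtrip_exact():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(12, 5))
    y = np.array([0, 1] * 6)
    model = fit_plsda(X, y, 3, autoscale=True)
    back = PLSDAModel.from_json(model.to_json())
    for attr in ("weights", "x_loadings", "y_loadings", "scores", "coef", "fitted_response"):
        np.testing.assert_array_equal(getattr(back, attr), getattr(model, attr))
    assert back.intercept == model.intercept
    np.testing.assert_array_equal(back.autoscale.means, model.autoscale.means)
    y_a, _ = predict(model, X)
    y_b, _ = predict(back, X)
    np.testing.assert_array_equal(y_a, y_b)
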