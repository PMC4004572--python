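"""Classifier contracts: tuning grids, probability outputs, determinism,
discriminant geometry, and the super learner's stacking behavior."""

import numpy as np
import pytest
from scipy import integrate

from conftest import make_feature_matrix
from lesionbench.classifiers import (
    BASE_ALGORITHM_NAMES,
    AlgorithmSpec,
    GaussianMixtureClassifier,
    TuningGrid,
    fit,
    fit_suite,
    make_learner,
    predict_proba,
    superlearner_fit,
    superlearner_predict,
)


@pytest.fixture(scope="module")
def blob_data():
    """Two overlapping 3-d Gaussian classes, 10% positives."""
    rng = np.random.default_rng(21)
    n = 400
    y = (rng.random(n) < 0.10).astype(int)
    X = rng.normal(0, 1, (n, 3)) + y[:, None] * np.array([1.5, -1.0, 2.0])
    return make_feature_matrix(X, y)


@pytest.fixture(scope="module")
def separable_data():
    """Widely separated classes: every algorithm should rank perfectly."""
    rng = np.random.default_rng(22)
    n = 300
    y = (rng.random(n) < 0.25).astype(int)
    X = rng.normal(0, 0.3, (n, 3)) + y[:, None] * 8.0
    return make_feature_matrix(X, y)


@pytest.mark.parametrize("name", BASE_ALGORITHM_NAMES)
def test_uniform_contract_and_determinism(blob_data, name):
    spec = AlgorithmSpec(name, seed=4)
    model = fit(spec, blob_data, folds=5)
    p = predict_proba(model, blob_data)
    assert p.shape == (blob_data.n_rows,)
    assert np.all((p >= 0) & (p <= 1))
    assert model.chosen_params in [dict(g) for g in
                                   TuningGrid.for_algorithm(name, 3).points]
    model2 = fit(spec, blob_data, folds=5)
    assert model2.chosen_params == model.chosen_params
    assert np.array_equal(predict_proba(model2, blob_data), p)


@pytest.mark.parametrize("name", BASE_ALGORITHM_NAMES)
def test_separable_data_ranks_perfectly(separable_data, name):
    from lesionbench.evaluation import roc_curve, scaled_pauc

    model = fit(AlgorithmSpec(name, seed=4), separable_data, folds=5)
    p = predict_proba(model, separable_data)
    assert scaled_pauc(roc_curve(p, separable_data.y), 0.10) == pytest.approx(1.0)


def test_knn_probabilities_are_vote_fractions(blob_data):
    learner = make_learner("knn", {"k": 10}, 0)
    X = blob_data.X.to_numpy()
    learner.fit(X, blob_data.y.astype(int))
    p = learner.predict_proba1(X)
    assert np.allclose(p * 10, np.round(p * 10))  # multiples of 1/k


def test_logistic_mean_probability_matches_prevalence(blob_data):
    model = fit(AlgorithmSpec("logistic_regression"), blob_data, folds=5)
    p = predict_proba(model, blob_data)
    # the ML score equations force mean fitted probability = prevalence
    assert p.mean() == pytest.approx(blob_data.y.mean(), abs=1e-6)


def test_constant_features_constant_probability():
    rng = np.random.default_rng(3)
    y = (rng.random(100) < 0.3).astype(int)
    fm = make_feature_matrix(np.ones((100, 2)), y)
    model = fit(AlgorithmSpec("logistic_regression"), fm, folds=5)
    p = predict_proba(model, fm)
    assert np.allclose(p, p[0])


def test_error_on_single_class_and_small_data():
    fm = make_feature_matrix(np.random.default_rng(0).normal(size=(50, 2)),
                             np.zeros(50))
    with pytest.raises(ValueError):
        fit(AlgorithmSpec("lda"), fm, folds=5)
    fm2 = make_feature_matrix(np.eye(4), [0, 1, 0, 1])
    with pytest.raises(ValueError):
        fit(AlgorithmSpec("lda"), fm2, folds=10)


def test_column_mismatch_rejected(blob_data):
    model = fit(AlgorithmSpec("lda"), blob_data, folds=5)
    other = make_feature_matrix(blob_data.X.to_numpy(), blob_data.y,
                                columns=["a", "b", "c"])
    with pytest.raises(ValueError):
        predict_proba(model, other)


def test_knn_infeasible_grid_point_skipped():
    rng = np.random.default_rng(11)
    y = np.r_[np.ones(10), np.zeros(40)].astype(int)
    fm = make_feature_matrix(rng.normal(0, 1, (50, 2)) + y[:, None], y)
    with pytest.warns(UserWarning, match="k=100"):
        model = fit(AlgorithmSpec("knn", seed=2), fm, folds=5)
    assert model.chosen_params["k"] in (1, 10)


def test_rf_grid_spans_feature_dimension():
    rng = np.random.default_rng(13)
    y = (rng.random(120) < 0.3).astype(int)
    X = rng.normal(0, 1, (120, 9)) + y[:, None]
    model = fit(AlgorithmSpec("random_forest", seed=1),
                make_feature_matrix(X, y), folds=3)
    assert len(model.training_summary["cv_scores"]) == 9
    assert 1 <= model.chosen_params["mtry"] <= 9


def test_lda_qda_recover_gaussian_boundary_direction():
    """Two spherical Gaussians: discriminant direction within 5 degrees."""
    rng = np.random.default_rng(17)
    n = 10_000
    delta = np.array([1.0, 2.0, -1.0])
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(0, 1, (n, 3)) + y[:, None] * delta

    def angle(u, v):
        c = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    lda = make_learner("lda", {}, 0)
    lda.fit(X, y)
    assert angle(lda.estimator.coef_.ravel(), delta) < 5

    qda = make_learner("qda", {}, 0)
    qda.fit(X, y)
    dmu = qda.estimator.means_[1] - qda.estimator.means_[0]
    assert angle(dmu, delta) < 5


def test_gmm_posteriors_and_density_normalization():
    rng = np.random.default_rng(19)
    y = (rng.random(300) < 0.4).astype(int)
    X = rng.normal(0, 1, (300, 1)) + y[:, None] * 2.5
    g = GaussianMixtureClassifier(seed=0).fit(X, y)
    post = g.predict_proba(X)
    assert np.allclose(post.sum(axis=1), 1.0)
    for c in (0, 1):
        dens = lambda t: np.exp(g.mixtures_[c].score_samples([[t]]))[0]
        total, _ = integrate.quad(dens, -15, 15)
        assert total == pytest.approx(1.0, abs=1e-3)


# ------------------------------------------------------------- super learner

class _ConstantLearner:
    def __init__(self, value):
        self.value = value

    def fit(self, X, y):
        return self

    def predict_proba1(self, X):
        return np.full(len(X), self.value)


class _OracleLearner:
    """Outputs the true class probability, stored in the first feature."""

    def fit(self, X, y):
        return self

    def predict_proba1(self, X):
        return X[:, 0]


class _NoiseLearner:
    def __init__(self, seed):
        self.seed = seed

    def fit(self, X, y):
        return self

    def predict_proba1(self, X):
        return np.random.default_rng([self.seed, len(X)]).random(len(X))


def test_superlearner_single_member_gets_weight_one(blob_data):
    sl = superlearner_fit(["lda"], blob_data, folds=5, seed=0)
    assert sl.weights.shape == (1,)
    assert sl.weights[0] == pytest.approx(1.0)


def test_superlearner_weights_on_simplex(blob_data):
    sl = superlearner_fit(["lda", "qda", "logistic_regression"], blob_data,
                          folds=5, seed=0)
    assert np.all(sl.weights >= 0)
    assert sl.weights.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all((sl.level_one >= 0) & (sl.level_one <= 1))


def test_superlearner_prediction_is_convex_combination(blob_data):
    lib = [("lo", lambda: _ConstantLearner(0.2)),
           ("hi", lambda: _ConstantLearner(0.9))]
    sl = superlearner_fit(lib, blob_data, folds=5, seed=0)
    p = superlearner_predict(sl, blob_data)
    assert np.all((p >= 0.2 - 1e-12) & (p <= 0.9 + 1e-12))

    same = [("a", lambda: _ConstantLearner(0.4)),
            ("b", lambda: _ConstantLearner(0.4))]
    sl2 = superlearner_fit(same, blob_data, folds=5, seed=0)
    assert np.allclose(superlearner_predict(sl2, blob_data), 0.4)


def test_superlearner_recovers_oracle_over_noise():
    """Stacking assigns nearly all weight to a true-probability oracle."""
    rng = np.random.default_rng(29)
    n = 5000
    p_true = rng.beta(1, 6, n)
    y = (rng.random(n) < p_true).astype(int)
    fm = make_feature_matrix(p_true[:, None], y, columns=["p_true"])
    lib = [("oracle", _OracleLearner), ("noise", lambda: _NoiseLearner(7))]
    sl = superlearner_fit(lib, fm, folds=10, seed=1)
    w = dict(zip(sl.labels, sl.weights))
    assert w["oracle"] > 0.9


def test_fit_suite_matches_single_fits(blob_data):
    suite = fit_suite(["lda", "knn"], blob_data, folds=5, seed=4)
    single = fit(AlgorithmSpec("knn", seed=4), blob_data, folds=5)
    assert suite["knn"].chosen_params == single.chosen_params
    assert np.array_equal(predict_proba(suite["knn"], blob_data),
                          predict_proba(single, blob_data))
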