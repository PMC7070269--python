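"""Node classifiers, instance weighting and the two-level hierarchy."""

import numpy as np
import pytest
from scipy.stats import norm

from oxiflow.classifiers import (
    BhcSpec,
    balance_weights,
    node_from_dict,
    node_to_dict,
    predict_bhc,
    predict_bhc_batch,
    predict_node,
    train_bhc,
    train_node,
)
from oxiflow.synthetic_data import Intensity


class TestBalanceWeights:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((9, 1), (10 / 18, 10 / 2)),
            ((5, 5), (1.0, 1.0)),
            ((3115, 550), None),  # the study's light/moderate imbalance
        ],
    )
    def test_per_class_sums_equal(self, counts, expected):
        y = np.r_[np.zeros(counts[0], int), np.ones(counts[1], int)]
        w = balance_weights(y)
        s0, s1 = w[y == 0].sum(), w[y == 1].sum()
        assert s0 == pytest.approx(s1, rel=1e-9)
        assert w.sum() == pytest.approx(len(y), rel=1e-9)
        if expected is not None:
            assert w[y == 0][0] == pytest.approx(expected[0])
            assert w[y == 1][0] == pytest.approx(expected[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_weights(np.zeros(5, int))


class TestLda:
    def test_symmetric_boundary_at_zero(self, rng):
        n = 10000
        X = np.r_[rng.normal(-1, 1, n), rng.normal(1, 1, n)].reshape(-1, 1)
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        model = train_node(X, y, algorithm="lda")
        grid = np.linspace(-0.2, 0.2, 4001).reshape(-1, 1)
        _, s = predict_node(model, grid)
        boundary = grid[np.argmin(np.abs(s - 0.5)), 0]
        assert abs(boundary) < 0.05

    def test_error_close_to_bayes_rate(self, rng):
        # equal-covariance Gaussians: Bayes error = Phi(-delta/2), delta = 2
        n = 4000
        Xtr = np.r_[rng.normal(-1, 1, (n, 2)), rng.normal(1, 1, (n, 2))]
        ytr = np.r_[np.zeros(n, int), np.ones(n, int)]
        Xte = np.r_[rng.normal(-1, 1, (n, 2)), rng.normal(1, 1, (n, 2))]
        yte = ytr.copy()
        model = train_node(Xtr, ytr, algorithm="lda")
        pred, _ = predict_node(model, Xte)
        err = np.mean(pred != yte)
        bayes = norm.cdf(-np.sqrt(2 * 2**2) / 2)  # d=2 independent shifts
        assert err <= bayes + 0.02

    def test_matches_sklearn_unweighted(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(300, 4))
        y = (X[:, 0] + 0.5 * X[:, 2] + 0.3 * rng.normal(size=300) > 0).astype(int)
        ours = train_node(X, y, algorithm="lda")
        ref = LinearDiscriminantAnalysis().fit(X, y)
        pred, _ = predict_node(ours, X)
        agreement = np.mean(pred == ref.predict(X))
        assert agreement >= 0.98

    def test_degenerate_covariance_ridged_not_failing(self):
        X = np.zeros((10, 3))
        X[:5, 0] = 1.0
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        model = train_node(X, y, algorithm="lda")  # two constant columns
        pred, _ = predict_node(model, X)
        assert np.array_equal(pred, y)


class TestTree:
    def test_perfect_on_threshold_separable(self, rng):
        X = rng.uniform(size=(400, 6))
        y = (X[:, 3] > 0.7).astype(int)
        model = train_node(X, y, algorithm="tree")
        pred, _ = predict_node(model, X)
        assert np.mean(pred == y) == 1.0

    def test_invariant_to_monotone_feature_transforms(self, rng):
        X = rng.normal(size=(300, 4))
        y = (X[:, 1] + 0.2 * rng.normal(size=300) > 0).astype(int)
        model = train_node(X, y, algorithm="tree")
        pred, _ = predict_node(model, X)
        Xm = X.copy()
        Xm[:, 1] = np.exp(X[:, 1])  # strictly monotone map of the split feature
        model_m = train_node(Xm, y, algorithm="tree")
        pred_m, _ = predict_node(model_m, Xm)
        assert np.array_equal(pred, pred_m)

    def test_pure_leaf_scores_extreme(self, rng):
        X = np.r_[np.zeros((50, 1)), np.ones((50, 1))]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        model = train_node(X, y, algorithm="tree")
        _, s0 = predict_node(model, np.array([0.0]))
        _, s1 = predict_node(model, np.array([1.0]))
        assert s0 < 0.05 and s1 > 0.95  # Laplace keeps them off exactly 0/1


class TestLogistic:
    def test_matches_sklearn(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(400, 3))
        y = (X @ np.array([1.0, -2.0, 0.5]) + 0.5 * rng.normal(size=400) > 0).astype(int)
        ours = train_node(X, y, algorithm="logistic")
        ref = LogisticRegression(C=1e6, tol=1e-10).fit(X, y)
        pred, _ = predict_node(ours, X)
        assert np.mean(pred == ref.predict(X)) >= 0.99


class TestNodeContract:
    def test_score_monotone_in_discriminant(self, rng):
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] > 0).astype(int)
        model = train_node(X, y, algorithm="lda")
        xs = rng.normal(size=(100, 3))
        _, scores = predict_node(model, xs)
        w = model.params.cov_inv @ (model.params.means[1] - model.params.means[0])
        disc = xs @ w
        order = np.argsort(disc)
        assert np.all(np.diff(scores[order]) >= -1e-12)

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(50, 4))
        y = (X[:, 0] > 0).astype(int)
        model = train_node(X, y, algorithm="lda")
        with pytest.raises(ValueError):
            predict_node(model, np.zeros(3))

    def test_unknown_algorithm_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises(ValueError):
            train_node(X, y, algorithm="svm")

    def test_serialization_round_trip(self, rng):
        X = rng.normal(size=(100, 5))
        y = (X[:, 2] > 0).astype(int)
        for alg in ("lda", "tree", "logistic"):
            model = train_node(X, y, algorithm=alg, feature_subset=[0, 2, 4])
            clone = node_from_dict(node_to_dict(model))
            _, s = predict_node(model, X)
            _, s2 = predict_node(clone, X)
            assert np.allclose(s, s2)


def _three_class_data(rng, n=120):
    """Well-separated 3-class data on two features."""
    X = rng.normal(scale=0.3, size=(3 * n, 4))
    y = np.repeat([0, 1, 2], n)
    X[:, 0] += y * 2.0
    X[:, 1] += (y == 2) * 1.5
    return X, y


class TestBhc:
    def test_default_spec_algorithms(self, rng):
        X, y = _three_class_data(rng)
        model = train_bhc(X, y, spec=BhcSpec(selection=None))
        assert model.phi1.algorithm == "tree"
        assert model.phi2.algorithm == "lda"

    def test_spec_override(self, rng):
        X, y = _three_class_data(rng)
        model = train_bhc(
            X, y, spec=BhcSpec(phi1_algorithm="lda", phi2_algorithm="lda",
                               selection=None)
        )
        assert model.phi1.algorithm == "lda"
        assert model.phi2.algorithm == "lda"

    def test_training_accuracy_on_separable_data(self, rng):
        X, y = _three_class_data(rng)
        model = train_bhc(X, y, spec=BhcSpec(selection={"seed": 0}))
        pred = predict_bhc_batch(model, X)
        assert np.mean(pred == y) >= 0.95

    def test_short_circuit_and_composition(self, rng):
        X, y = _three_class_data(rng)
        model = train_bhc(X, y, spec=BhcSpec(selection=None))
        # sedentary prediction leaves phi2 untouched
        sed_x = X[y == 0][0]
        cls, scores = predict_bhc(model, sed_x)
        if cls == Intensity.SEDENTARY:
            assert scores["phi2"] is None
        # batch prediction equals manual two-step composition
        for x in X[rng.choice(len(X), size=50, replace=False)]:
            lab1, _ = predict_node(model.phi1, x)
            if lab1 == 0:
                expected = 0
            else:
                lab2, _ = predict_node(model.phi2, x)
                expected = 2 if lab2 == 1 else 1
            assert predict_bhc_batch(model, x[None, :])[0] == expected
            assert int(predict_bhc(model, x)[0]) == expected

    def test_missing_class_rejected(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        with pytest.raises(ValueError):
            train_bhc(X, y)
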