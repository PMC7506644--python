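"""SMOTE balancing, the four classifiers, and the CV protocol."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics.pairwise import polynomial_kernel
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

import geomexpr as gx
from geomexpr.classify import make_estimator


class TestSmote:
    def test_paper_counts_balance_to_104(self, rng):
        counts = {"SU": 63, "SA": 66, "HA": 99, "FE": 62, "DI": 64, "AN": 70}
        y = np.concatenate([[c] * n for c, n in counts.items()])
        X = rng.normal(size=(len(y), 8))
        Xb, yb = gx.smote_balance(X, y, 104, rng=rng)
        classes, out = np.unique(yb, return_counts=True)
        assert dict(zip(classes, out)) == {c: 104 for c in counts}
        assert len(yb) == 624

    def test_originals_retained_and_noop_when_balanced(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat(["a", "b", "c"], 10)
        Xb, yb = gx.smote_balance(X, y, 10, rng=rng)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)
        Xb, yb = gx.smote_balance(X, y, 15, rng=rng)
        assert np.array_equal(Xb[:30], X)

    def test_synthetic_points_on_same_class_segments(self, rng):
        """Every synthetic row must lie on a segment between two
        original rows of its own class (convexity of SMOTE)."""
        X = rng.normal(size=(20, 2))
        y = np.repeat(["a", "b"], 10)
        Xb, yb = gx.smote_balance(X, y, 25, rng=rng)
        for s, cls in zip(Xb[20:], yb[20:]):
            Xc = X[y == cls]
            on_segment = False
            for i in range(len(Xc)):
                for j in range(len(Xc)):
                    if i == j:
                        continue
                    d = Xc[j] - Xc[i]
                    t = np.dot(s - Xc[i], d) / np.dot(d, d)
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(Xc[i] + t * d - s) < 1e-9:
                        on_segment = True
            assert on_segment

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(11, 3))
        y = np.array(["a"] * 10 + ["b"])
        with pytest.raises(ValueError, match="single member"):
            gx.smote_balance(X, y, 10, rng=rng)

    def test_shrinking_is_not_allowed(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError, match="oversamples"):
            gx.smote_balance(X, y, 5, rng=rng)


class TestClassifiers:
    def test_1nn_self_prediction_perfect(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.choice(["AN", "HA", "SU"], size=30)
        while len(np.unique(y)) < 2:  # pragma: no cover
            y = rng.choice(["AN", "HA", "SU"], size=30)
        pred, _, _ = gx.train_predict(gx.KNN1, X, y, X)
        assert np.array_equal(pred, y)

    def test_kernel_matrix_matches_direct_evaluation(self, rng):
        """SVM2/SVM3 differ only in the kernel exponent (1 + x.y)^d."""
        X = rng.normal(size=(12, 4))
        for spec in (gx.SVM2, gx.SVM3):
            est = make_estimator(
                gx.ClassifierSpec(family="svm_poly", degree=spec.degree, standardize=False),
                n_features=4,
            )
            K_lib = polynomial_kernel(X, X, degree=est.degree, gamma=est.gamma, coef0=est.coef0)
            K_direct = (1.0 + X @ X.T) ** spec.degree
            assert np.allclose(K_lib, K_direct, atol=1e-10)

    def test_one_vs_one_vote_tally(self, rng):
        """Multiclass prediction equals the argmax of pairwise votes
        (ties to the lowest class index), reconstructed by hand from
        the one-vs-one decision values."""
        X = rng.normal(size=(60, 4))
        y = np.repeat([0, 1, 2], 20)
        X[y == 1, 0] += 3.0
        X[y == 2, 1] += 3.0
        clf = SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=1.0,
                  decision_function_shape="ovo").fit(X, y)
        dec = clf.decision_function(X)  # (n, 3) pairwise: (0,1), (0,2), (1,2)
        pairs = [(0, 1), (0, 2), (1, 2)]
        votes = np.zeros((len(X), 3))
        for col, (i, j) in enumerate(pairs):
            votes[:, i] += dec[:, col] > 0
            votes[:, j] += dec[:, col] <= 0
        assert np.array_equal(clf.predict(X), votes.argmax(axis=1))

    def test_cubic_svm_agrees_with_qp_oracle(self):
        """Decision values of the cubic-kernel SVM on a 4-point toy
        match a quadratic program solved directly on the Gram matrix."""
        X = np.array([[0.0, 0.0], [2.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        C = 1.0
        K = (1.0 + X @ X.T) ** 3
        Q = np.outer(y, y) * K

        def negdual(a):
            return 0.5 * a @ Q @ a - a.sum()

        res = minimize(
            negdual,
            np.zeros(4),
            jac=lambda a: Q @ a - np.ones(4),
            bounds=[(0, C)] * 4,
            constraints={"type": "eq", "fun": lambda a: a @ y},
            method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 500},
        )
        alpha = res.x
        inside = (alpha > 1e-6) & (alpha < C - 1e-6)
        b = np.mean([y[j] - (alpha * y) @ K[:, j] for j in np.where(inside)[0]])
        oracle = (alpha * y) @ K + b

        clf = SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=C, tol=1e-8).fit(X, y)
        assert np.allclose(clf.decision_function(X), oracle, atol=1e-4)

    def test_subspace_ensemble_averages_learner_scores(self, rng):
        """Ensemble probabilities equal the mean of the per-learner
        1-NN votes on their own feature subsets."""
        X = rng.normal(size=(24, 6))
        y = np.repeat(["a", "b"], 12)
        X[y == "b"] += 1.0
        spec = gx.ClassifierSpec(
            family="subspace_knn_ensemble", n_learners=15, subspace_dims=2, standardize=False
        )
        est = make_estimator(spec, n_features=6, seed=5)
        est.fit(X, y)
        manual = np.zeros((len(X), 2))
        for learner, feats in zip(est.estimators_, est.estimators_features_):
            manual += learner.predict_proba(X[:, feats])
        manual /= len(est.estimators_)
        assert np.allclose(est.predict_proba(X), manual, atol=1e-12)

    def test_subspace_dims_default_is_half(self, rng):
        est = make_estimator(gx.EKNN, n_features=89, seed=0)
        bag = est.steps[-1][1]
        assert bag.max_features == round(89 / 2)
        assert bag.n_estimators == 200
        assert isinstance(bag.estimator, KNeighborsClassifier)
        assert bag.estimator.n_neighbors == 1

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError, match="feature count"):
            gx.train_predict(gx.KNN1, X, y, rng.normal(size=(5, 3)))


class OracleStub(BaseEstimator, ClassifierMixin):
    """Predicts the true (encoded) label via a lookup from row bytes.

    ``evaluate`` fits classifiers on labels encoded as integers in the
    fixed display order, so the lookup maps each row to that index.
    """

    def __init__(self, lookup=None):
        self.lookup = lookup

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.array([self.lookup[np.asarray(row).tobytes()] for row in X])


class RandomGuessStub(BaseEstimator, ClassifierMixin):
    """Uniform random guesses over the training classes (test only).

    The guess stream is re-seeded from the content of each prediction
    batch so that every fold gets independent draws (a fixed stream
    replayed against near-identical fold label patterns would not
    average to chance level).
    """

    def __init__(self, seed=0):
        self.seed = seed

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        import zlib

        rng = np.random.default_rng([self.seed, zlib.crc32(np.asarray(X).tobytes())])
        return rng.choice(self.classes_, size=len(X))


def balanced_data(n_per=12, d=5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["SU", "SA", "HA", "FE", "DI", "AN"], n_per)
    return rng.normal(size=(len(y), d)), y


class TestEvaluate:
    def test_oracle_stub_scores_100_with_identity_confusion(self):
        X, y = balanced_data()
        lookup = {
            np.asarray(row).tobytes(): gx.DISPLAY_ORDER.index(label)
            for row, label in zip(X, y)
        }
        report = gx.evaluate(OracleStub(lookup), X, y, n_repetitions=3, seed=0)
        assert report.rep_accuracies == [100.0, 100.0, 100.0]
        assert np.allclose(report.confusion, 100 * np.eye(6))
        assert report.class_order == list(gx.DISPLAY_ORDER)

    def test_random_guess_near_one_sixth(self):
        X, y = balanced_data(n_per=10)
        report = gx.evaluate(RandomGuessStub(seed=4), X, y, n_repetitions=50, seed=1)
        assert report.mean == pytest.approx(100 / 6, abs=3.0)

    def test_summary_order_statistics(self, small_matrix):
        report = gx.evaluate(gx.KNN1, small_matrix.X, small_matrix.y, n_repetitions=4, seed=2)
        assert report.min <= report.median <= report.max
        assert report.min <= report.mean <= report.max
        assert report.std >= 0

    def test_confusion_rows_sum_to_100(self, small_matrix):
        report = gx.evaluate(gx.SVM3, small_matrix.X, small_matrix.y, n_repetitions=2, seed=3)
        assert np.allclose(report.confusion.sum(axis=1), 100.0)
        assert report.confusion_counts.sum() == 2 * len(small_matrix.y)

    def test_fixed_seed_bit_identical_report(self, small_matrix):
        r1 = gx.evaluate(gx.SVM3, small_matrix.X, small_matrix.y, n_repetitions=2, seed=9)
        r2 = gx.evaluate(gx.SVM3, small_matrix.X, small_matrix.y, n_repetitions=2, seed=9)
        assert r1.rep_accuracies == r2.rep_accuracies
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_small_class_advises_balancing(self, rng):
        X = rng.normal(size=(24, 3))
        y = np.array(["a"] * 20 + ["b"] * 4)
        with pytest.raises(ValueError, match="balance"):
            gx.evaluate(gx.KNN1, X, y, n_repetitions=1)

    def test_smote_within_folds_balances_training_splits(self, rng):
        """The leakage-free variant balances inside each fold and
        still produces a well-formed report on unbalanced input."""
        y = np.repeat(["SU", "SA", "HA"], [12, 15, 20])
        X = rng.normal(size=(len(y), 4))
        X[y == "SA", 0] += 4.0
        X[y == "HA", 1] += 4.0
        report = gx.evaluate(
            gx.KNN1, X, y, n_repetitions=2, seed=0, smote_within_folds=20
        )
        assert len(report.rep_accuracies) == 2
        assert np.allclose(report.confusion.sum(axis=1), 100.0)
        with pytest.raises(ValueError, match="below the largest"):
            gx.evaluate(gx.KNN1, X, y, n_repetitions=1, smote_within_folds=10)

    def test_stratified_folds_balanced_within_one(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat(["a", "b", "c"], [12, 15, 23])
        X = np.zeros((len(y), 2))
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        global_counts = {c: n for c, n in zip(*np.unique(y, return_counts=True))}
        for _, te in skf.split(X, y):
            classes, counts = np.unique(y[te], return_counts=True)
            for c, n in zip(classes, counts):
                assert abs(n - global_counts[c] / 10) <= 1
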