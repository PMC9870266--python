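import numpy as np
import pytest
from sklearn.base import clone

from btfsc.pnn import PNNClassifier, pnn_posterior, pnn_predict, pnn_train, select_sigma


def pnn_oracle_posteriors(F_train, y_train, sigma, X_query):
    """Independent scalar-loop kernel-density Bayes classifier."""
    F_train = np.asarray(F_train, dtype=np.float64)
    classes = np.unique(y_train)
    means = F_train.mean(axis=0)
    stds = F_train.std(axis=0)
    keep = stds > 0
    Z = (F_train[:, keep] - means[keep]) / stds[keep]
    out = []
    for x in np.atleast_2d(X_query):
        z = (np.asarray(x)[keep] - means[keep]) / stds[keep]
        scores = []
        for c in classes:
            members = [Z[i] for i in range(len(Z)) if y_train[i] == c]
            total = 0.0
            for p in members:
                d2 = float(sum((z - p) ** 2))
                total += np.exp(-d2 / (2.0 * sigma**2))
            prior = sum(1 for t in y_train if t == c) / len(y_train)
            scores.append(prior * total / len(members))
        scores = np.array(scores)
        out.append(scores / scores.sum())
    return np.array(out)


class TestTraining:
    def test_patterns_and_priors(self):
        F = np.array([[0.0, 1], [0.1, 2], [1.0, 3], [1.1, 4.0]])
        y = np.array([0, 0, 1, 1])
        model = pnn_train(F, y)
        assert model.patterns_.shape == (4, 2)
        assert np.allclose(model.priors_, [0.5, 0.5])

    def test_constant_column_dropped_with_warning(self):
        F = np.array([[0.0, 5.0], [0.1, 5.0], [1.0, 5.0], [1.1, 5.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="constant"):
            model = pnn_train(F, y)
        assert model.patterns_.shape == (4, 1)

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(0)
        F = rng.random((10, 3))
        y = np.array([0, 1] * 5)
        a, b = pnn_train(F, y), pnn_train(F, y)
        assert np.array_equal(a.patterns_, b.patterns_)

    def test_undersized_class_rejected(self):
        with pytest.raises(ValueError):
            pnn_train(np.zeros((3, 2)), np.array([0, 0, 1]))


class TestPosterior:
    def test_posteriors_sum_to_one(self, rng):
        F = rng.random((12, 4))
        y = np.array([0, 1, 2] * 4)
        model = pnn_train(F, y, sigma=0.7)
        proba = model.predict_proba(rng.random((5, 4)))
        assert np.abs(proba.sum(axis=1) - 1.0).max() < 1e-12

    def test_tiny_sigma_concentrates_on_matching_pattern(self, rng):
        F = rng.random((8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = pnn_train(F, y, sigma=1e-3)
        assert pnn_posterior(model, F[5])[1] > 0.999

    def test_two_class_1d_closed_form(self):
        F = np.array([[-1.0], [-1.2], [1.0], [1.2]])
        y = np.array([0, 0, 1, 1])
        model = pnn_train(F, y, sigma=0.5)
        ours = pnn_posterior(model, np.array([0.9]))
        oracle = pnn_oracle_posteriors(F, y, 0.5, [[0.9]])[0]
        assert np.allclose(ours, oracle, atol=1e-12)
        assert ours[1] > 0.5

    def test_matches_bruteforce_oracle_on_small_datasets(self, rng):
        for trial in range(5):
            n = int(rng.integers(6, 21))
            d = int(rng.integers(1, 5))
            F = rng.normal(0, 1, size=(n, d))
            y = np.array([0, 1] * (n // 2) + [0] * (n % 2))
            if np.bincount(y).min() < 2:
                continue
            sigma = float(rng.uniform(0.2, 2.0))
            model = pnn_train(F, y, sigma=sigma)
            Q = rng.normal(0, 1, size=(4, d))
            assert np.allclose(
                model.predict_proba(Q),
                pnn_oracle_posteriors(F, y, sigma, Q),
                atol=1e-10,
            )

    def test_large_sigma_posteriors_approach_priors(self):
        F = np.array([[0.0], [0.2], [1.0], [1.2], [1.4]])
        y = np.array([0, 0, 1, 1, 1])
        model = pnn_train(F, y, sigma=1e6)
        proba = pnn_posterior(model, np.array([0.6]))
        assert np.abs(proba - np.array([0.4, 0.6])).max() < 1e-3

    def test_dimension_mismatch_rejected(self):
        model = pnn_train(np.zeros((4, 2)) + np.arange(4)[:, None], [0, 0, 1, 1])
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((1, 5)))


class TestPrediction:
    def test_training_set_recovery_with_small_sigma(self, rng):
        F = rng.random((10, 3))
        y = np.array([0, 1] * 5)
        model = pnn_train(F, y, sigma=1e-3)
        assert np.array_equal(pnn_predict(model, F), y)

    def test_midpoint_tie_breaks_to_lower_class(self):
        F = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = pnn_train(F, y, sigma=0.5)
        assert pnn_predict(model, np.array([[0.0]]))[0] == 0

    def test_separated_gaussians_high_accuracy(self):
        """d=10 features, class means 2 within-class sigmas apart in every
        dimension (Mahalanobis separation 2*sqrt(10), Bayes rate ~0.999):
        a seeded 200/200 split must exceed 0.9 test accuracy."""
        rng = np.random.default_rng(0)
        d = 10
        mu = np.zeros(d)
        mu2 = np.full(d, 2.0)
        Xtr = np.concatenate(
            [rng.normal(mu, 1.0, (200, d)), rng.normal(mu2, 1.0, (200, d))]
        )
        ytr = np.array([0] * 200 + [1] * 200)
        Xte = np.concatenate(
            [rng.normal(mu, 1.0, (100, d)), rng.normal(mu2, 1.0, (100, d))]
        )
        yte = np.array([0] * 100 + [1] * 100)
        model = pnn_train(Xtr, ytr, sigma=1.0)
        acc = np.mean(pnn_predict(model, Xte) == yte)
        assert acc >= 0.9

    def test_sklearn_clone_compatible(self):
        est = PNNClassifier(sigma=0.3)
        assert clone(est).get_params()["sigma"] == 0.3


class TestSigmaSelection:
    def test_singleton_grid_returned(self):
        assert select_sigma(np.zeros((4, 1)), [0, 0, 1, 1], grid=[0.7]) == 0.7

    def test_deterministic(self, rng):
        F = rng.random((40, 3))
        y = np.array([0, 1] * 20)
        a = select_sigma(F, y, folds=4, seed=3)
        b = select_sigma(F, y, folds=4, seed=3)
        assert a == b

    def test_separable_data_achieves_perfect_cv(self):
        rng = np.random.default_rng(1)
        F = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        sigma = select_sigma(F, y, folds=5, seed=0)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        accs = [
            np.mean(
                pnn_predict(pnn_train(F[tr], y[tr], sigma), F[te]) == y[te]
            )
            for tr, te in skf.split(F, y)
        ]
        assert np.mean(accs) == 1.0

    def test_excessive_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            select_sigma(np.zeros((4, 1)), [0, 0, 1, 1], grid=[0.1, 1.0], folds=3)
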