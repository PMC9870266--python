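"""Probabilistic neural network (PNN) classification.

A PNN is a kernel-density Bayes classifier: every standardized training
vector becomes a Gaussian pattern unit, a summation layer averages the
kernel responses per class (scaled by class priors), and the decision
layer takes the maximum-posterior class.  The only tunable parameter is
the kernel bandwidth sigma, selected here by stratified cross-validation.

Deep feature learning happens upstream in the hybrid feature extractor;
the classifier itself is the classical Specht architecture over those
vectors.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold


class PNNClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian-kernel probabilistic neural network.

    Parameters
    ----------
    sigma : kernel bandwidth (> 0) in standardized feature units.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels.
    patterns_ : standardized training vectors.
    pattern_class_ : index into classes_ per pattern.
    priors_ : class prior probabilities (training frequencies).
    feature_means_, feature_stds_ : standardization parameters.
    kept_features_ : boolean mask of non-constant training columns
        (constant columns are dropped with a warning).
    """

    def __init__(self, sigma: float = 0.5) -> None:
        self.sigma = sigma

    def fit(self, X: np.ndarray, y: Sequence) -> "PNNClassifier":
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        classes, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx, minlength=classes.size)
        if np.any(counts < 2):
            raise ValueError("every class needs at least 2 training samples")
        means = X.mean(axis=0)
        stds = X.std(axis=0)
        keep = stds > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant feature column(s)",
                stacklevel=2,
            )
        if not keep.any():
            raise ValueError("all feature columns are constant")
        self.classes_ = classes
        self.feature_means_ = means[keep]
        self.feature_stds_ = stds[keep]
        self.kept_features_ = keep
        self.patterns_ = (X[:, keep] - self.feature_means_) / self.feature_stds_
        self.pattern_class_ = y_idx
        self.priors_ = counts / counts.sum()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "patterns_"):
            raise RuntimeError("classifier is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class posteriors: prior-weighted mean Gaussian kernel response
        per class, normalized per query.  A query so remote that every
        kernel underflows falls back to the class priors."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.kept_features_.size:
            raise ValueError(
                f"expected {self.kept_features_.size} features, got {X.shape[1]}"
            )
        Z = (X[:, self.kept_features_] - self.feature_means_) / self.feature_stds_
        # (n_query, n_patterns) squared distances in standardized space.
        d2 = (
            (Z * Z).sum(axis=1)[:, None]
            - 2.0 * Z @ self.patterns_.T
            + (self.patterns_ * self.patterns_).sum(axis=1)[None, :]
        )
        kernel = np.exp(-np.maximum(d2, 0.0) / (2.0 * self.sigma**2))
        n_classes = self.classes_.size
        scores = np.empty((Z.shape[0], n_classes))
        for c in range(n_classes):
            members = self.pattern_class_ == c
            scores[:, c] = self.priors_[c] * kernel[:, members].mean(axis=1)
        total = scores.sum(axis=1, keepdims=True)
        degenerate = total[:, 0] <= 0.0
        posteriors = np.where(total > 0, scores / np.maximum(total, 1e-300), 0.0)
        if degenerate.any():
            posteriors[degenerate] = self.priors_
        return posteriors[0] if single else posteriors

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Maximum-posterior class; ties resolve to the lower class index."""
        proba = np.atleast_2d(self.predict_proba(X))
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Functional facade
# ---------------------------------------------------------------------------


def pnn_train(F: np.ndarray, y: Sequence, sigma: float = 0.5) -> PNNClassifier:
    """Train a PNN: standardize, store patterns, set priors from frequencies."""
    return PNNClassifier(sigma=sigma).fit(F, y)


def pnn_posterior(model: PNNClassifier, x: np.ndarray) -> np.ndarray:
    """Posterior class-probability vector for one feature vector."""
    return model.predict_proba(np.asarray(x, dtype=np.float64))


def pnn_predict(model: PNNClassifier, F: np.ndarray) -> np.ndarray:
    """Predicted labels for a feature matrix."""
    return model.predict(F)


def select_sigma(
    F: np.ndarray,
    y: Sequence,
    grid: Optional[List[float]] = None,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Pick the kernel bandwidth by stratified k-fold cross-validation.

    Returns the grid value with the best mean CV accuracy; ties go to the
    smaller sigma.  Deterministic under the seed.
    """
    if grid is None:
        grid = [0.05, 0.1, 0.2, 0.5, 1.0, 2.0]
    if not grid:
        raise ValueError("sigma grid must be nonempty")
    if len(grid) == 1:
        return float(grid[0])
    F = np.asarray(F, dtype=np.float64)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(F, y))
    best_sigma, best_acc = None, -1.0
    for sigma in sorted(grid):
        accs = []
        for train_idx, test_idx in splits:
            model = PNNClassifier(sigma=sigma).fit(F[train_idx], y[train_idx])
            accs.append(float(np.mean(model.predict(F[test_idx]) == y[test_idx])))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_sigma, best_acc = sigma, acc
    return float(best_sigma)
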