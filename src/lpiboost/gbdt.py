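"""Multi-output gradient-boosted regression trees.

The ensemble is a stage-wise additive expansion: a constant initial
prediction f0 (column-wise target means) plus K shrunken regression trees,
each fitted by least squares to the current pseudo-residuals (the negative
gradient of the squared loss, i.e. targets minus the running prediction).
Under squared loss the stage-weight line search is exact and is absorbed
into a constant shrinkage factor.

Trees are CART regression trees with vector-valued leaves; the split score
is the total variance reduction summed over output dimensions, thresholds
sit at midpoints of consecutive sorted feature values, and every leaf holds
at least one sample.  Fits are fully deterministic for a given
``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data


class AdditiveTreeEnsemble:
    """Low-level additive ensemble: f0 + shrinkage * sum of trees.

    Supports incremental growth (``update``) against moving targets, which
    is what the layered model needs: a mapping keeps its accumulated trees
    across epochs and appends residual-fitting trees toward each new
    pseudo-label.
    """

    def __init__(self, shrinkage: float, random_state: int = 0):
        self.shrinkage = float(shrinkage)
        self.random_state = int(random_state)
        self.init_: np.ndarray | None = None
        self.trees_: list[DecisionTreeRegressor] = []

    @property
    def n_trees(self) -> int:
        return len(self.trees_)

    def initialize(self, targets: np.ndarray) -> None:
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        self.init_ = targets.mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.init_ is None:
            raise RuntimeError("ensemble not initialised")
        out = np.broadcast_to(self.init_, (X.shape[0], self.init_.size)).copy()
        for tree in self.trees_:
            out += self.shrinkage * np.atleast_2d(tree.predict(X).T).T
        return out

    def update(self, X: np.ndarray, targets: np.ndarray, n_trees: int,
               max_depth: int) -> np.ndarray:
        """Append ``n_trees`` residual-fitting trees toward ``targets``.

        Returns the training sum-of-squares toward ``targets`` after each
        appended tree (length ``n_trees``), which is non-increasing for
        shrinkage in (0, 2).
        """
        X = np.asarray(X, dtype=float)
        targets = np.asarray(targets, dtype=float)
        if targets.ndim == 1:
            targets = targets[:, None]
        if self.init_ is None:
            self.initialize(targets)
        current = self.predict(X)
        losses = np.empty(n_trees)
        for k in range(n_trees):
            residual = targets - current
            tree = DecisionTreeRegressor(
                max_depth=max_depth, min_samples_leaf=1,
                random_state=self.random_state + self.n_trees)
            tree.fit(X, residual)
            self.trees_.append(tree)
            current = current + self.shrinkage * np.atleast_2d(
                tree.predict(X).T).T
            losses[k] = float(((targets - current) ** 2).sum())
        return losses


class GradientBoostedTrees(RegressorMixin, BaseEstimator):
    """Gradient-boosted multi-output regression trees (squared loss).

    Parameters
    ----------
    n_estimators : int
        Number of boosting rounds K (one tree per round).
    max_depth : int
        Depth limit of each regression tree.
    learning_rate : float
        Shrinkage applied to every tree's contribution.  The squared-loss
        line search for the stage weight is exact and folded in here.
    random_state : int
        Seed for deterministic split-score tie-breaking inside the trees.

    Attributes
    ----------
    init_ : ndarray of shape (n_outputs,)
        Column-wise target means (the stage-0 prediction).
    trees_ : list of fitted trees, length ``n_estimators``.
    train_losses_ : ndarray of shape (n_estimators,)
        Training sum-of-squares after each boosting round (non-increasing).
    """

    def __init__(self, n_estimators: int = 5, max_depth: int = 5,
                 learning_rate: float = 0.1, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, multi_output=True, y_numeric=True,
                             dtype=float)
        if X.shape[0] < 2:
            raise ValueError("fitting requires at least 2 samples")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        y2 = y if y.ndim == 2 else y[:, None]
        self._y_was_1d = y.ndim == 1
        self.n_outputs_ = y2.shape[1]
        self._ensemble = AdditiveTreeEnsemble(
            self.learning_rate, random_state=self.random_state or 0)
        self._ensemble.initialize(y2)
        self.train_losses_ = self._ensemble.update(
            X, y2, self.n_estimators, self.max_depth)
        self.init_ = self._ensemble.init_
        self.trees_ = self._ensemble.trees_
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        out = self._ensemble.predict(X)
        return out.ravel() if self._y_was_1d else out

    def staged_predict(self, X):
        """Yield predictions after each boosting round (including round 0,
        the constant initial fit)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        out = np.broadcast_to(self.init_, (X.shape[0], self.n_outputs_)).copy()
        yield out.ravel() if self._y_was_1d else out.copy()
        for tree in self.trees_:
            out = out + self.learning_rate * np.atleast_2d(tree.predict(X).T).T
            yield out.ravel() if self._y_was_1d else out.copy()
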