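"""Multi-layer deep architecture of gradient-boosted trees.

The model stacks GBDT "forward mappings" F_1..F_L (L = number of hidden
layers, each producing a fixed-width representation o_i) under a linear
sigmoid head, and trains them without backpropagation by target
propagation:

* **Initialisation** — each F_i is seeded by a single very shallow tree
  round fitted from o_{i-1} to Gaussian noise targets N(0, epsilon^2 I) of
  the layer's width; each inverse mapping G_i (i >= 2) is seeded likewise
  from F_i(o_{i-1}) back to o_{i-1}.  The head is a regularised logistic
  regression on the top output.
* **Top pseudo-label** — the top layer's target is its current output moved
  against the loss gradient, p = o - alpha * dL/do.  In the default
  ``head_gradient`` mode L is the per-sample binary cross-entropy through
  the sigmoid head, giving p = o - alpha * (sigma(z) - y) W.  A ``literal``
  mode instead applies a squared loss between each output coordinate and the
  0/1 label, giving p = o - alpha * (o - y) (so alpha = 1 returns the label
  in every coordinate).
* **Inverse phase** (top layer down to layer 2) — G_i is boosted toward
  reconstructing noise-perturbed inputs from F_i's outputs, then the pseudo-
  label is propagated down: p_{i-1} = G_i(p_i).
* **Forward phase** (bottom up) — each F_i is boosted toward its
  pseudo-label p_i and the layer outputs are refreshed.
* The head is refitted on the new top output each epoch.

All stochastic steps (noise targets, noise injection) consume one seeded
generator, so a fixed ``random_state`` gives bit-identical training logs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted, validate_data

from .gbdt import AdditiveTreeEnsemble

_INIT_TREE_DEPTH = 2  # "very tiny trees" for the noise initialisation


class _Layer:
    """State of one hidden GBDT layer: forward mapping, optional inverse
    mapping, current output and current pseudo-label."""

    __slots__ = ("forward", "inverse", "output", "pseudo_label", "width")

    def __init__(self, width: int):
        self.width = width
        self.forward: AdditiveTreeEnsemble | None = None
        self.inverse: AdditiveTreeEnsemble | None = None
        self.output: np.ndarray | None = None
        self.pseudo_label: np.ndarray | None = None


def binary_cross_entropy(scores: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of sigmoid scores against 0/1 labels."""
    eps = 1e-12
    s = np.clip(scores, eps, 1 - eps)
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


class DeepGBDTClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier built from stacked gradient-boosted tree layers
    trained by target propagation, with a logistic head.

    Parameters
    ----------
    hidden_dims : tuple of int, default (16, 16)
        Output widths of the GBDT layers (the published architecture is
        input-16-16-output).
    n_epochs : int, default 15
        Target-propagation iterations after initialisation.
    n_rounds : int, default 3
        Additive boosting rounds per mapping per epoch.
    num_boost_round : int, default 5
        Trees per boosting round, so each mapping gains
        ``n_rounds * num_boost_round`` trees per epoch.
    max_depth : int, default 5
        Tree depth for all mapping updates (initialisation trees use
        depth 2).
    shrinkage : float, default 0.1
        Contribution of each appended tree (the mapping-update step size).
    target_lr : float, default 1.0
        Learning rate alpha of the top pseudo-label move.
    epsilon : float, default 0.3
        Scale sigma of the Gaussian noise used both for the initialisation
        targets and for the inverse-phase input perturbation.
    pseudo_label_mode : {"head_gradient", "literal"}
        How the top pseudo-label is derived (see module docstring).
    head_C : float, default 1.0
        Inverse L2 regularisation strength of the logistic head.
    diagnostic_identity : bool, default False
        Skip the tree layers entirely and fit the head on the raw input; the
        model then reduces exactly to logistic regression (a plumbing
        check).
    random_state : int or None
        Seed for all noise draws and tree tie-breaking.

    Attributes
    ----------
    layers_ : list of layer states (forward/inverse ensembles, outputs).
    head_ : fitted ``LogisticRegression``.
    history_ : list of per-epoch dicts with the global loss and per-layer
        forward/inverse reconstruction losses (entry 0 is the initialised
        model).
    """

    def __init__(self, hidden_dims=(16, 16), n_epochs: int = 15,
                 n_rounds: int = 3, num_boost_round: int = 5,
                 max_depth: int = 5, shrinkage: float = 0.1,
                 target_lr: float = 1.0, epsilon: float = 0.3,
                 pseudo_label_mode: str = "head_gradient",
                 head_C: float = 1.0, diagnostic_identity: bool = False,
                 random_state: int | None = None):
        self.hidden_dims = hidden_dims
        self.n_epochs = n_epochs
        self.n_rounds = n_rounds
        self.num_boost_round = num_boost_round
        self.max_depth = max_depth
        self.shrinkage = shrinkage
        self.target_lr = target_lr
        self.epsilon = epsilon
        self.pseudo_label_mode = pseudo_label_mode
        self.head_C = head_C
        self.diagnostic_identity = diagnostic_identity
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _validate_params_(self) -> None:
        if len(self.hidden_dims) < 1 or any(d < 1 for d in self.hidden_dims):
            raise ValueError("hidden_dims needs >= 1 layer, all widths >= 1")
        if self.target_lr <= 0:
            raise ValueError("target_lr must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.n_epochs < 0 or self.n_rounds < 1 or self.num_boost_round < 1:
            raise ValueError("n_epochs >= 0, n_rounds/num_boost_round >= 1")
        if self.pseudo_label_mode not in ("head_gradient", "literal"):
            raise ValueError("pseudo_label_mode must be 'head_gradient' or "
                             "'literal'")

    def _fit_head(self, o_top: np.ndarray, y: np.ndarray) -> None:
        self.head_ = LogisticRegression(C=self.head_C, solver="lbfgs",
                                        tol=1e-8, max_iter=1000)
        self.head_.fit(o_top, y)

    def _head_scores(self, o_top: np.ndarray) -> np.ndarray:
        z = o_top @ self.head_.coef_[0] + self.head_.intercept_[0]
        return expit(z)

    def _init_layers(self, X: np.ndarray, y: np.ndarray) -> None:
        """Phase I: seed every mapping with one shallow tree round toward
        Gaussian noise targets and compute the initial outputs."""
        seed = 0 if self.random_state is None else int(self.random_state)
        self._rng = np.random.default_rng(seed)
        self.layers_ = [_Layer(w) for w in self.hidden_dims]
        prev = X
        for idx, layer in enumerate(self.layers_):
            noise_targets = self._rng.normal(
                0.0, self.epsilon, size=(X.shape[0], layer.width))
            layer.forward = AdditiveTreeEnsemble(
                self.shrinkage, random_state=seed + 1000 * (idx + 1))
            layer.forward.initialize(noise_targets)
            layer.forward.update(prev, noise_targets, 1, _INIT_TREE_DEPTH)
            out = layer.forward.predict(prev)
            if idx >= 1:
                layer.inverse = AdditiveTreeEnsemble(
                    self.shrinkage, random_state=seed + 1000 * (idx + 1) + 500)
                layer.inverse.initialize(prev)
                layer.inverse.update(out, prev, 1, _INIT_TREE_DEPTH)
            layer.output = out
            prev = out

    # -- spec-level operations ----------------------------------------- #

    def top_pseudo_label(self, y: np.ndarray) -> np.ndarray:
        """Pseudo-label for the top GBDT layer: output moved one
        ``target_lr`` step against the loss gradient."""
        check_is_fitted(self, "head_")
        o = self.layers_[-1].output
        if self.pseudo_label_mode == "literal":
            # squared loss between each output coordinate and the label
            return o - self.target_lr * (o - np.asarray(y, float)[:, None])
        s = self._head_scores(o)
        grad = (s - y)[:, None] * self.head_.coef_[0][None, :]
        return o - self.target_lr * grad

    def update_inverse(self, i: int, p_i: np.ndarray) -> np.ndarray:
        """Boost G_i toward reconstructing noise-perturbed inputs of layer
        ``i`` (1-based, >= 2) and propagate the pseudo-label down.

        Returns p_{i-1} = G_i(p_i); records the reconstruction loss.
        """
        if i < 2:
            raise ValueError("layer 1 has no inverse mapping")
        layer = self.layers_[i - 1]
        below = self.layers_[i - 2].output
        noisy = below + self._rng.normal(0.0, self.epsilon, size=below.shape)
        f_out = layer.forward.predict(noisy)
        losses = layer.inverse.update(
            f_out, noisy, self.n_rounds * self.num_boost_round,
            self.max_depth)
        self._epoch_inv_losses[i] = losses / below.shape[0]
        return layer.inverse.predict(p_i)

    def update_forward(self, i: int, p_i: np.ndarray) -> np.ndarray:
        """Boost F_i toward its pseudo-label and refresh the layer output.

        Returns the new o_i; records the reconstruction loss trace.
        """
        layer = self.layers_[i - 1]
        if p_i is None:
            raise ValueError(f"layer {i} has no pseudo-label")
        below = X_in = (self._X_train if i == 1
                        else self.layers_[i - 2].output)
        losses = layer.forward.update(
            below, p_i, self.n_rounds * self.num_boost_round, self.max_depth)
        self._epoch_forw_losses[i] = losses / below.shape[0]
        layer.output = layer.forward.predict(X_in)
        layer.pseudo_label = p_i
        return layer.output

    # ------------------------------------------------------------------ #

    def fit(self, X, y):
        self._validate_params_()
        X, y = validate_data(self, X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("DeepGBDTClassifier is a binary classifier; got "
                             f"{len(self.classes_)} class(es)")
        y01 = (y == self.classes_[1]).astype(float)
        if self.diagnostic_identity:
            self._fit_head(X, y01)
            self.history_ = []
            return self

        self._X_train = X
        self._init_layers(X, y01)
        self._fit_head(self.layers_[-1].output, y01)
        self.history_ = [{
            "epoch": 0,
            "global_loss": binary_cross_entropy(
                self._head_scores(self.layers_[-1].output), y01),
            "forward_losses": {}, "inverse_losses": {},
        }]

        n_layers = len(self.layers_)
        for epoch in range(1, self.n_epochs + 1):
            self._epoch_forw_losses: dict[int, np.ndarray] = {}
            self._epoch_inv_losses: dict[int, np.ndarray] = {}
            # pseudo-label at the top, then inverse updates propagating down
            p = self.top_pseudo_label(y01)
            self.layers_[-1].pseudo_label = p
            pseudo = {n_layers: p}
            for i in range(n_layers, 1, -1):
                pseudo[i - 1] = self.update_inverse(i, pseudo[i])
            # forward updates bottom-up
            for i in range(1, n_layers + 1):
                self.update_forward(i, pseudo[i])
            # refit head on the refreshed top representation
            self._fit_head(self.layers_[-1].output, y01)
            self.history_.append({
                "epoch": epoch,
                "global_loss": binary_cross_entropy(
                    self._head_scores(self.layers_[-1].output), y01),
                "forward_losses": {k: v.tolist() for k, v
                                   in self._epoch_forw_losses.items()},
                "inverse_losses": {k: v.tolist() for k, v
                                   in self._epoch_inv_losses.items()},
            })
        return self

    def transform_layers(self, X: np.ndarray) -> np.ndarray:
        """Propagate X through the forward mappings to the top
        representation."""
        out = X
        for layer in self.layers_:
            out = layer.forward.predict(out)
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "head_")
        X = validate_data(self, X, reset=False, dtype=float)
        if self.diagnostic_identity:
            return self.head_.predict_proba(X)
        s = self._head_scores(self.transform_layers(X))
        return np.column_stack([1 - s, s])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X):
        proba = self.predict_proba(X)
        return np.log(proba[:, 1] / np.clip(proba[:, 0], 1e-12, None))
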