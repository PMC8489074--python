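"""Dimension reduction and pair-vector assembly.

Entity descriptors (lncRNA and protein separately) are reduced to ``d``
principal components; an interacting-pair vector is the concatenation
[lncRNA scores || protein scores] of width exactly 2d.  When an entity set
is rank-deficient (fewer samples than requested components — e.g. 35
proteins against d = 100) the score matrix is zero-padded so the classifier
input width stays fixed across datasets and folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import InteractionDataset


class PaddedPCA(TransformerMixin, BaseEstimator):
    """Mean-centred PCA with a fixed output width.

    Parameters
    ----------
    n_components : int
        Requested dimension d.  The effective rank is
        ``min(d, n_samples - 1, n_features)``; score columns beyond it are
        zero.
    scale : bool, default False
        Standardise features to unit variance before the decomposition
        (recommended when descriptor blocks mix raw counts with
        frequencies; zero-variance features are left unscaled).

    Components are sign-canonicalised so each axis's largest-magnitude
    loading is positive, making the fit deterministic.
    """

    def __init__(self, n_components: int = 100, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA requires at least 2 samples")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.d_effective_ = min(self.n_components, X.shape[0] - 1,
                                X.shape[1])
        self.scaler_ = StandardScaler(with_std=self.scale).fit(X)
        Z = self.scaler_.transform(X)
        self._pca = PCA(n_components=self.d_effective_, svd_solver="full")
        self._pca.fit(Z)
        # canonical signs: largest-|loading| entry of each axis positive
        comps = self._pca.components_
        flip = np.sign(comps[np.arange(comps.shape[0]),
                             np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comps * flip[:, None]
        self.explained_variance_ = self._pca.explained_variance_
        self.mean_ = self.scaler_.mean_
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        scores = self.scaler_.transform(X) @ self.components_.T
        if self.d_effective_ < self.n_components:
            pad = np.zeros((X.shape[0],
                            self.n_components - self.d_effective_))
            scores = np.hstack([scores, pad])
        return scores

    def inverse_transform(self, scores):
        check_is_fitted(self)
        scores = np.asarray(scores, dtype=float)[:, :self.d_effective_]
        Z = scores @ self.components_
        return self.scaler_.inverse_transform(Z)


def fit_reduction(features: np.ndarray, d: int,
                  scale: bool = False) -> PaddedPCA:
    """Fit a :class:`PaddedPCA` reduction model (functional wrapper)."""
    return PaddedPCA(n_components=d, scale=scale).fit(features)


def transform(model: PaddedPCA, features: np.ndarray) -> np.ndarray:
    """Project features onto a fitted reduction model (width padded to d)."""
    return model.transform(features)


@dataclass
class PairDataset:
    """Concatenated 2d-dimensional pair vectors with 0/1 labels and
    provenance (lncRNA id, protein id) per row."""

    X: np.ndarray
    y: np.ndarray
    pair_ids: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not (self.X.shape[0] == self.y.shape[0] == len(self.pair_ids)):
            raise ValueError("row count mismatch between X, y and pair ids")


def make_pairs(lnc_scores: np.ndarray, prot_scores: np.ndarray,
               dataset: InteractionDataset,
               pairs: Sequence[tuple[str, str]]) -> PairDataset:
    """Assemble labelled pair vectors x = [lncRNA scores || protein scores].

    ``lnc_scores`` / ``prot_scores`` rows are aligned with the dataset's id
    lists; ``pairs`` are (lncrna_id, protein_id) tuples and unknown ids
    raise ``KeyError``.
    """
    rows_l = np.array([dataset.lnc_index(a) for a, _ in pairs], dtype=int)
    rows_p = np.array([dataset.prot_index(b) for _, b in pairs], dtype=int)
    X = np.hstack([lnc_scores[rows_l], prot_scores[rows_p]])
    y = dataset.Y[rows_l, rows_p].astype(int)
    return PairDataset(X=X, y=y, pair_ids=[tuple(p) for p in pairs])
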