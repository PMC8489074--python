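"""Balanced negative sampling, cold-start cross-validation and metrics.

Three 5-fold protocols are supported:

* **CV1** holds out whole lncRNAs: no test pair's lncRNA appears in any
  training pair (prediction for a new lncRNA).
* **CV2** is the symmetric protocol on proteins.
* **CV3** partitions the labelled pairs directly (prediction for unseen
  pairs of known entities).

Negatives are drawn uniformly without replacement from the zero cells of
the interaction matrix, as many as there are positives (balanced design),
and are resampled on every repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import InteractionDataset

logger = logging.getLogger(__name__)

MODES = ("cv1", "cv2", "cv3")
METRICS = ("precision", "recall", "accuracy", "f1", "auc", "aupr")


@dataclass
class LabeledPairs:
    """Index-based labelled pair sample (positives plus sampled
    negatives)."""

    lnc_idx: np.ndarray
    prot_idx: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


def sample_negatives(dataset: InteractionDataset, seed=None,
                     n: int | None = None) -> np.ndarray:
    """Uniformly sample ``n`` (default: the positive count) distinct zero
    cells of Y, returned as an (n, 2) index array."""
    rng = np.random.default_rng(seed)
    zeros = np.argwhere(dataset.Y == 0)
    if n is None:
        n = int(dataset.Y.sum())
    if n < 1:
        raise ValueError("dataset has no positives to balance against")
    if len(zeros) < n:
        raise ValueError(f"only {len(zeros)} zero cells available, "
                         f"need {n} negatives")
    pick = rng.choice(len(zeros), size=n, replace=False)
    return zeros[pick]


def make_labeled_pairs(dataset: InteractionDataset, seed=None
                       ) -> LabeledPairs:
    """Positives plus an equal number of freshly sampled negatives."""
    pos = dataset.positive_pairs()
    neg = sample_negatives(dataset, seed=seed)
    lnc = np.concatenate([pos[:, 0], neg[:, 0]])
    prot = np.concatenate([pos[:, 1], neg[:, 1]])
    y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledPairs(lnc_idx=lnc, prot_idx=prot, y=y)


@dataclass
class FoldPlan:
    """k-fold split plan over entities (CV1/CV2) or pairs (CV3).

    ``folds`` holds (train_indices, test_indices) into the labelled pair
    arrays; ``entity_folds`` holds the held-out entity indices for CV1/CV2.
    """

    mode: str
    k: int
    seed: object
    folds: list[tuple[np.ndarray, np.ndarray]]
    entity_folds: list[np.ndarray] = field(default_factory=list)


def make_folds(dataset: InteractionDataset, mode: str, k: int,
               seed=None, pairs: LabeledPairs | None = None) -> FoldPlan:
    """Build a :class:`FoldPlan`; fold sizes differ by at most one.

    ``pairs`` defaults to a fresh balanced sample seeded consistently with
    the folds.
    """
    mode = mode.lower()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = make_labeled_pairs(dataset, seed=rng)
    n_pairs = len(pairs)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    entity_folds: list[np.ndarray] = []
    if mode == "cv3":
        if n_pairs < k:
            raise ValueError(f"k={k} exceeds the {n_pairs} labelled pairs")
        order = rng.permutation(n_pairs)
        for chunk in np.array_split(order, k):
            test = np.sort(chunk)
            train = np.setdiff1d(order, chunk)
            folds.append((train, test))
    else:
        entity_idx = pairs.lnc_idx if mode == "cv1" else pairs.prot_idx
        n_entities = (dataset.shape[0] if mode == "cv1"
                      else dataset.shape[1])
        if n_entities < k:
            raise ValueError(f"k={k} exceeds the {n_entities} entities")
        order = rng.permutation(n_entities)
        for chunk in np.array_split(order, k):
            held_out = np.sort(chunk)
            entity_folds.append(held_out)
            mask = np.isin(entity_idx, held_out)
            folds.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    return FoldPlan(mode=mode, k=k, seed=seed, folds=folds,
                    entity_folds=entity_folds)


def compute_metrics(y_true, scores, threshold: float = 0.5) -> dict:
    """Precision, recall, accuracy, F1 (at ``threshold``), AUC and AUPR.

    F1 is 0 when TP = 0; precision/recall are 0 when their denominators are
    empty.  AUC/AUPR require both classes in ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC/AUPR undefined: y_true has a single class")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {
        "precision": precision, "recall": recall, "accuracy": accuracy,
        "f1": f1,
        "auc": float(roc_auc_score(y_true, scores)),
        "aupr": float(average_precision_score(y_true, scores)),
    }


@dataclass
class MetricsReport:
    """Per-(repeat, fold) metric rows with repeat-averaged summaries."""

    mode: str
    per_run: list[dict]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_run)

    def mean(self) -> dict[str, float]:
        df = self.frame()
        return {m: float(df[m].mean()) for m in METRICS}

    def std(self) -> dict[str, float]:
        df = self.frame()
        return {m: float(df[m].std(ddof=0)) for m in METRICS}

    def summary(self) -> dict[str, dict[str, float]]:
        mean, std = self.mean(), self.std()
        return {m: {"mean": mean[m], "std": std[m]} for m in METRICS}


def _pair_matrix(lnc_scores: np.ndarray, prot_scores: np.ndarray,
                 pairs: LabeledPairs, idx: np.ndarray) -> np.ndarray:
    return np.hstack([lnc_scores[pairs.lnc_idx[idx]],
                      prot_scores[pairs.prot_idx[idx]]])


def run_experiment(dataset: InteractionDataset, lnc_scores: np.ndarray,
                   prot_scores: np.ndarray, estimator, mode: str = "cv3",
                   k: int = 5, repeats: int = 20, seed=None,
                   threshold: float = 0.5,
                   fit_callback=None) -> MetricsReport:
    """Repeat-averaged cold-start evaluation of a classifier.

    Every repeat resamples the balanced negatives and the fold assignment;
    every fold clones ``estimator`` (reseeding it when it exposes a
    ``random_state`` parameter), trains on the training pairs and scores
    the held-out pairs.  Degenerate test folds with a single class are
    skipped with a warning and excluded from the averages.
    ``fit_callback`` (if given) receives each fitted per-fold model, e.g.
    to inspect training histories.
    """
    master = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for repeat, rep_seed in enumerate(master.spawn(repeats)):
        neg_seed, fold_seed, est_seed = rep_seed.spawn(3)
        pairs = make_labeled_pairs(dataset, seed=neg_seed)
        plan = make_folds(dataset, mode, k, seed=fold_seed, pairs=pairs)
        fold_states = est_seed.generate_state(k)
        for f, (train, test) in enumerate(plan.folds):
            y_train, y_test = pairs.y[train], pairs.y[test]
            if (len(np.unique(y_test)) < 2 or len(np.unique(y_train)) < 2
                    or len(test) == 0):
                logger.warning("repeat %d fold %d (%s): degenerate fold "
                               "skipped", repeat, f, mode)
                continue
            model = clone(estimator)
            if "random_state" in model.get_params():
                model.set_params(random_state=int(fold_states[f] % 2**31))
            model.fit(_pair_matrix(lnc_scores, prot_scores, pairs, train),
                      y_train)
            if fit_callback is not None:
                fit_callback(model)
            scores = model.predict_proba(
                _pair_matrix(lnc_scores, prot_scores, pairs, test))[:, 1]
            row = compute_metrics(y_test, scores, threshold=threshold)
            row.update({"repeat": repeat, "fold": f})
            rows.append(row)
    return MetricsReport(mode=mode, per_run=rows)


def rank_pairs(model, dataset: InteractionDataset, lnc_scores: np.ndarray,
               prot_scores: np.ndarray, top: int = 50) -> pd.DataFrame:
    """Score every (lncRNA, protein) cell and return the ``top`` pairs with
    their known/unknown status — the candidate list for case-study style
    exports."""
    n_l, n_p = dataset.shape
    li, pi = np.meshgrid(np.arange(n_l), np.arange(n_p), indexing="ij")
    li, pi = li.ravel(), pi.ravel()
    X = np.hstack([lnc_scores[li], prot_scores[pi]])
    scores = model.predict_proba(X)[:, 1]
    order = np.argsort(-scores, kind="stable")[:top]
    return pd.DataFrame({
        "lncrna_id": [dataset.lncrna_ids[i] for i in li[order]],
        "protein_id": [dataset.protein_ids[j] for j in pi[order]],
        "score": scores[order],
        "known": dataset.Y[li[order], pi[order]].astype(bool),
    })
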