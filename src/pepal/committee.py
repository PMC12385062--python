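"""Per-view binary-relevance committees and ensemble decisions.

One multi-label model is trained per feature view; each model is a set of
L independent binary probabilistic classifiers (binary relevance).  The
committee's stacked predictions form a V x N x L tensor of probabilities
and thresholded votes, which feeds both the vote-entropy query strategy
and the mean-probability ensemble decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .featurize import FeatureView
from .io import LabelMatrix

#: Probability used (after clipping) by the degenerate single-class fallback.
FALLBACK_CLIP = (0.01, 0.99)


class _ConstantClassifier:
    """Fallback when a label has a single class among labeled samples."""

    def __init__(self, prob: float):
        self.prob = float(np.clip(prob, *FALLBACK_CLIP))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = np.full(len(X), self.prob)
        return np.column_stack([1 - p, p])


def default_base_learner(seed: int) -> LogisticRegression:
    """Regularized linear probabilistic classifier (the default member)."""
    return LogisticRegression(solver="liblinear", C=1.0, random_state=seed)


class BinaryRelevance:
    """L independent binary classifiers over one feature matrix."""

    def __init__(self, base_factory: Callable[[int], object], seed: int = 0):
        self.base_factory = base_factory
        self.seed = seed
        self.estimators_: list[object] = []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "BinaryRelevance":
        self.estimators_ = []
        for j in range(Y.shape[1]):
            yj = Y[:, j]
            if yj.min() == yj.max():  # single class: constant prior fallback
                self.estimators_.append(_ConstantClassifier(float(yj.mean())))
            else:
                clf = self.base_factory(self.seed)
                clf.fit(X, yj)
                self.estimators_.append(clf)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """N x L matrix of positive-class probabilities."""
        cols = [est.predict_proba(X)[:, 1] for est in self.estimators_]
        return np.column_stack(cols)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """N x L logit-scale decision values (logit of the fallback prob)."""
        cols = []
        for est in self.estimators_:
            if hasattr(est, "decision_function"):
                cols.append(est.decision_function(X))
            else:
                p = est.predict_proba(X)[:, 1]
                cols.append(np.log(p / (1 - p)))
        return np.column_stack(cols)


@dataclass
class ViewCommittee:
    """V fitted binary-relevance models, one per feature view."""

    members: list[BinaryRelevance]
    view_names: list[str]
    fitted: bool = False

    @property
    def n_views(self) -> int:
        return len(self.members)


@dataclass
class PredictionTensor:
    """V x N x L committee outputs: probabilities and thresholded votes.

    A vote is positive iff the probability is >= 0.5 (ties go positive).
    """

    probs: np.ndarray
    votes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("prediction tensor must be V x N x L")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities outside [0, 1]")
        if self.votes is None:
            self.votes = (self.probs >= 0.5).astype(np.int8)


def train_committee(
    views: Sequence[FeatureView],
    labels: LabelMatrix,
    labeled_idx: Sequence[int],
    seed: int = 0,
    base_factory: Callable[[int], object] = default_base_learner,
) -> ViewCommittee:
    """Fit one binary-relevance model per view on the labeled rows only."""
    idx = np.asarray(labeled_idx)
    if idx.size == 0:
        raise ValueError("labeled set is empty")
    Y = labels.values[idx]
    members = []
    for view in views:
        model = BinaryRelevance(base_factory, seed=seed)
        model.fit(view.matrix[idx], Y)
        members.append(model)
    return ViewCommittee(
        members=members, view_names=[v.name for v in views], fitted=True
    )


def predict_tensor(
    committee: ViewCommittee,
    views: Sequence[FeatureView],
    idx: Sequence[int],
) -> PredictionTensor:
    """Predict the requested rows under every committee member."""
    if not committee.fitted:
        raise RuntimeError("committee is not fitted")
    rows = np.asarray(idx)
    probs = np.stack(
        [m.predict_proba(v.matrix[rows]) for m, v in zip(committee.members, views)]
    )
    return PredictionTensor(probs=probs)


def ensemble_decide(tensor: PredictionTensor) -> tuple[np.ndarray, np.ndarray]:
    """Average member probabilities and threshold at 0.5 (ties positive).

    Returns (hard N x L in {0,1}, scores N x L in [0,1]); the scores are
    the ranking inputs for all threshold-free metrics.
    """
    if tensor.probs.size == 0:
        raise ValueError("empty prediction tensor")
    scores = tensor.probs.mean(axis=0)
    return (scores >= 0.5).astype(np.int8), scores


def per_view_auc(
    views: Sequence[FeatureView],
    labels: LabelMatrix,
    labeled_idx: Sequence[int],
    test_idx: Sequence[int],
    seed: int = 0,
    base_factory: Callable[[int], object] = default_base_learner,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-view label-wise AUC on a held-out fold.

    Trains each view's model on ``labeled_idx`` only and scores
    ``test_idx``.  Returns (V x L AUC table with NaN for single-class test
    labels, V macro-AUC averages over defined cells, V micro-AUC values).
    """
    labeled = np.asarray(labeled_idx)
    test = np.asarray(test_idx)
    if np.intersect1d(labeled, test).size:
        raise ValueError("test fold overlaps the labeled set")
    committee = train_committee(views, labels, labeled, seed, base_factory)
    tensor = predict_tensor(committee, views, test)
    Y = labels.values[test]
    V, _, L = tensor.probs.shape
    table = np.full((V, L), np.nan)
    micro = np.empty(V)
    for v in range(V):
        for j in range(L):
            yj = Y[:, j]
            if yj.min() != yj.max():
                table[v, j] = roc_auc_score(yj, tensor.probs[v, :, j])
        micro[v] = roc_auc_score(Y.ravel(), tensor.probs[v].ravel())
    macro = np.nanmean(table, axis=1)
    return table, macro, micro


def majority_vote_error(
    n_members: int, eps: float, n_trials: int, seed: int
) -> float:
    """Monte-Carlo majority-vote error for independent members with a
    common error rate ``eps`` on a binary task (analytic-bound check)."""
    rng = np.random.default_rng(seed)
    wrong = rng.random((n_trials, n_members)) < eps
    return float((wrong.sum(axis=1) * 2 > n_members).mean())
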