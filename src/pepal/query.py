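"""Sample-selection strategies for pool-based active learning.

The committee strategy ranks unlabeled samples by vote entropy summed
across labels — the standard negated form, so larger means more committee
disagreement — and takes the top lambda.  Random, label-cardinality
inconsistency (LCI) and maximum-margin uncertainty (MMU) baselines share
the same batch contract.  Exact score ties are broken by a seeded shuffle
before a stable sort, so early iterations with many identical scores stay
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .committee import PredictionTensor
from .io import LabelMatrix


@dataclass
class QueryBatch:
    """Ordered selection of pool indices plus the scores that ranked them."""

    selected_idx: np.ndarray
    scores: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        self.selected_idx = np.asarray(self.selected_idx, dtype=int)
        if len(set(self.selected_idx.tolist())) != self.selected_idx.size:
            raise ValueError("duplicate indices in query batch")


def vote_entropy(votes: np.ndarray) -> float:
    """Disagreement of one sample's V x L binary votes.

    Sum over labels of the entropy of the vote split, natural log,
    0*log(0) = 0.  Zero iff every label is unanimous; each evenly split
    label contributes log 2.
    """
    votes = np.asarray(votes)
    if votes.ndim != 2 or votes.shape[0] < 1:
        raise ValueError("votes must be V x L with V >= 1")
    V = votes.shape[0]
    p1 = votes.sum(axis=0) / V
    total = 0.0
    for p in (p1, 1.0 - p1):
        nz = p[p > 0]
        total -= float((nz * np.log(nz)).sum())
    return total


def batch_vote_entropy(votes: np.ndarray) -> np.ndarray:
    """Vectorized vote entropy for a V x N x L vote tensor -> N scores."""
    V = votes.shape[0]
    p1 = votes.sum(axis=0) / V  # (N, L)
    ent = np.zeros(p1.shape)
    for p in (p1, 1.0 - p1):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        ent -= term
    return ent.sum(axis=1)


def _top_by_score(
    pool_idx: np.ndarray,
    scores: np.ndarray,
    lam: int,
    seed: int,
    strategy: str,
    descending: bool = True,
) -> QueryBatch:
    pool_idx = np.asarray(pool_idx)
    if pool_idx.size == 0:
        raise ValueError("pool is empty")
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if lam > pool_idx.size:
        warnings.warn("lam exceeds pool size; returning entire pool", stacklevel=3)
        lam = pool_idx.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pool_idx.size)
    key = -scores[perm] if descending else scores[perm]
    order = perm[np.argsort(key, kind="stable")]
    sel = order[:lam]
    return QueryBatch(
        selected_idx=pool_idx[sel], scores=scores, strategy=strategy
    )


def qbc_query(
    tensor: PredictionTensor, pool_idx: np.ndarray, lam: int, seed: int
) -> QueryBatch:
    """Top-lambda pool members by committee vote entropy, descending."""
    ent = batch_vote_entropy(tensor.votes)
    if ent.shape[0] != len(pool_idx):
        raise ValueError("tensor rows must align with pool_idx")
    return _top_by_score(np.asarray(pool_idx), ent, lam, seed, "qbc")


def random_query(pool_idx: np.ndarray, lam: int, seed: int) -> QueryBatch:
    """Uniform sample without replacement from the pool."""
    pool_idx = np.asarray(pool_idx)
    if pool_idx.size == 0:
        raise ValueError("pool is empty")
    if lam > pool_idx.size:
        warnings.warn("lam exceeds pool size; returning entire pool", stacklevel=2)
        lam = pool_idx.size
    rng = np.random.default_rng(seed)
    sel = rng.choice(pool_idx.size, size=lam, replace=False)
    return QueryBatch(
        selected_idx=pool_idx[sel],
        scores=np.zeros(pool_idx.size),
        strategy="random",
    )


def lci_query(
    single_model_scores: np.ndarray,
    labels: LabelMatrix,
    labeled_idx: np.ndarray,
    pool_idx: np.ndarray,
    lam: int,
    seed: int,
) -> QueryBatch:
    """Label-cardinality inconsistency on a single concatenated-view model.

    score(x) = | #{j : p_j(x) >= 0.5} - mean label cardinality of the
    labeled set |; the most inconsistent candidates are selected.
    """
    pool_idx = np.asarray(pool_idx)
    mean_card = float(labels.values[np.asarray(labeled_idx)].sum(axis=1).mean())
    pred_card = (np.asarray(single_model_scores)[pool_idx] >= 0.5).sum(axis=1)
    scores = np.abs(pred_card - mean_card)
    return _top_by_score(pool_idx, scores, lam, seed, "lci")


def mmu_margins(decision_values: np.ndarray) -> np.ndarray:
    """Per-sample separation margin between positive- and negative-side
    decision values (d >= 0 counts as the positive side).

    margin = min over positive-side d minus max over negative-side d;
    an empty side falls back to +/- min|d|.
    """
    d = np.asarray(decision_values, dtype=float)
    margins = np.empty(d.shape[0])
    for i, row in enumerate(d):
        pos = row[row >= 0]
        neg = row[row < 0]
        fallback = np.abs(row).min()
        lo = pos.min() if pos.size else fallback
        hi = neg.max() if neg.size else -fallback
        margins[i] = lo - hi
    return margins


def mmu_query(
    single_model_scores: np.ndarray,
    pool_idx: np.ndarray,
    lam: int,
    seed: int,
) -> QueryBatch:
    """Maximum-margin uncertainty: select the lambda smallest margins.

    ``single_model_scores`` are logit-scale decision values (N x L) from
    the concatenated-view model.
    """
    pool_idx = np.asarray(pool_idx)
    margins = mmu_margins(np.asarray(single_model_scores)[pool_idx])
    return _top_by_score(pool_idx, margins, lam, seed, "mmu", descending=False)
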