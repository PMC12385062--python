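"""Independent brute-force reference implementations used only by tests.

Everything here is written as explicit loops straight from the metric
definitions, deliberately ignoring the vectorized implementations they
check.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_macro_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mean per-label pairwise concordance; ties earn half credit;
    single-class labels skipped."""
    aucs = []
    for j in range(y.shape[1]):
        pos = [scores[i, j] for i in range(len(y)) if y[i, j] == 1]
        neg = [scores[i, j] for i in range(len(y)) if y[i, j] == 0]
        if not pos or not neg:
            continue
        hits = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        aucs.append(hits / (len(pos) * len(neg)))
    return float(np.mean(aucs)) if aucs else float("nan")


def oracle_micro_auc(scores: np.ndarray, y: np.ndarray) -> float:
    pos, neg = [], []
    for i in range(y.shape[0]):
        for j in range(y.shape[1]):
            (pos if y[i, j] == 1 else neg).append(scores[i, j])
    hits = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return hits / (len(pos) * len(neg))


def oracle_aps(scores: np.ndarray, y: np.ndarray) -> float:
    """Sample-wise average precision over relevant labels; a label's rank
    is the number of labels scored at least as high."""
    terms = []
    for i in range(y.shape[0]):
        rel = [j for j in range(y.shape[1]) if y[i, j] == 1]
        if not rel:
            continue
        def rank(j):
            return sum(1 for k in range(y.shape[1]) if scores[i, k] >= scores[i, j])
        precs = []
        for j in rel:
            rj = rank(j)
            above = sum(1 for jp in rel if rank(jp) <= rj)
            precs.append(above / rj)
        terms.append(sum(precs) / len(precs))
    return float(np.mean(terms))


def oracle_one_error(scores: np.ndarray, y: np.ndarray) -> float:
    errs = 0
    for i in range(y.shape[0]):
        top = 0
        for j in range(1, y.shape[1]):
            if scores[i, j] > scores[i, top]:  # ties keep the lowest index
                top = j
        if y[i, top] == 0:
            errs += 1
    return errs / y.shape[0]


def oracle_ranking_loss(scores: np.ndarray, y: np.ndarray) -> float:
    """Fraction of discordant (relevant, irrelevant) pairs; ties count as
    losses; samples lacking either side are excluded."""
    terms = []
    for i in range(y.shape[0]):
        rel = [j for j in range(y.shape[1]) if y[i, j] == 1]
        irr = [j for j in range(y.shape[1]) if y[i, j] == 0]
        if not rel or not irr:
            continue
        losses = sum(1 for j in rel for k in irr if scores[i, j] <= scores[i, k])
        terms.append(losses / (len(rel) * len(irr)))
    return float(np.mean(terms)) if terms else 0.0


def oracle_vote_entropy(votes: np.ndarray) -> float:
    """Direct evaluation of the negated vote-entropy sum over labels."""
    V, L = votes.shape
    total = 0.0
    for j in range(L):
        c1 = int(votes[:, j].sum())
        for c in (c1, V - c1):
            if c > 0:
                total -= (c / V) * math.log(c / V)
    return total


def oracle_ppct(pssm: np.ndarray, psfm: np.ndarray, max_lag: int = 5) -> np.ndarray:
    """Explicit triple loop over lags and residue pairs with the logistic
    squash applied element-wise."""
    L = pssm.shape[1]
    s = 1.0 / (1.0 + np.exp(-pssm))
    out = np.zeros((max_lag, 20, 20))
    for g in range(1, max_lag + 1):
        if L <= g:
            continue
        for u in range(20):
            for v in range(20):
                acc = 0.0
                for i in range(L - g):
                    acc += s[u, i] * psfm[v, i + g]
                out[g - 1, u, v] = acc / (L - g)
    return out.ravel()
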