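"""Multi-label ranking metrics and learning-curve areas.

All five metrics are rank-based (invariant to strictly monotone score
transforms).  Tie conventions are fixed and documented:

* AUC concordance gives score ties half credit (the standard Mann-Whitney
  convention), so a constant scorer earns 0.5 rather than a spurious 1.0.
* Ranking loss counts ``f(relevant) <= f(irrelevant)`` as a loss.
* One-error argmax ties break toward the lowest label index.
* A relevant label's rank is the number of labels scored at least as high.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import LabelMatrix


@dataclass(frozen=True)
class MetricsReport:
    macro_auc: float
    micro_auc: float
    aps: float
    one_error: float
    ranking_loss: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _concordance(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mean pairwise concordance of (positive, negative) score pairs,
    ties earning half credit."""
    if pos.size == 0 or neg.size == 0:
        return np.nan
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0) + 0.5 * (diff == 0)).mean())


def compute_metrics(scores: np.ndarray, truth: LabelMatrix | np.ndarray) -> MetricsReport:
    """Evaluate ranking scores against binary ground truth.

    ``scores`` is N x L real; ``truth`` the aligned binary matrix.  Labels
    with a single class are skipped by macro-AUC; samples whose relevant or
    irrelevant label set is empty are excluded from the ranking-loss
    denominator; every sample needs >= 1 relevant label for APS/one-error.
    """
    y = truth.values if isinstance(truth, LabelMatrix) else np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != y.shape:
        raise ValueError(f"scores {scores.shape} vs truth {y.shape}")
    n, L = y.shape

    # macro-AUC: mean per-label concordance
    per_label = [
        _concordance(scores[y[:, j] == 1, j], scores[y[:, j] == 0, j])
        for j in range(L)
    ]
    per_label = [a for a in per_label if not np.isnan(a)]
    macro = float(np.mean(per_label)) if per_label else np.nan

    # micro-AUC: concordance over all flattened (sample, label) pairs
    flat_s, flat_y = scores.ravel(), y.ravel()
    micro = _concordance(flat_s[flat_y == 1], flat_s[flat_y == 0])

    # ranks: r[n, j] = #labels scored >= score of label j for sample n
    ranks = (scores[:, :, None] <= scores[:, None, :]).sum(axis=2)

    aps_terms = []
    rl_terms = []
    one_err = 0
    for i in range(n):
        rel = np.flatnonzero(y[i] == 1)
        irr = np.flatnonzero(y[i] == 0)
        if rel.size:
            prec = [
                (ranks[i, rel] <= ranks[i, j]).sum() / ranks[i, j] for j in rel
            ]
            aps_terms.append(float(np.mean(prec)))
            if y[i, int(np.argmax(scores[i]))] == 0:
                one_err += 1
        if rel.size and irr.size:
            losses = (scores[i, rel][:, None] <= scores[i, irr][None, :]).sum()
            rl_terms.append(losses / (rel.size * irr.size))

    aps = float(np.mean(aps_terms)) if aps_terms else np.nan
    rloss = float(np.mean(rl_terms)) if rl_terms else 0.0
    one_error = one_err / n if n else np.nan
    return MetricsReport(
        macro_auc=macro,
        micro_auc=micro,
        aps=aps,
        one_error=float(one_error),
        ranking_loss=float(rloss),
    )


def curve_area(curve: list[tuple[float, float]] | np.ndarray) -> float:
    """Trapezoidal area under a learning curve.

    ``curve`` is a list of (labeled_fraction, metric) points with strictly
    increasing x in [0, 1].  The integral runs over the traversed x-range
    and is not divided by its width.
    """
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two curve points")
    x, v = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("curve x-values must be strictly increasing")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("curve x-values must lie in [0, 1]")
    return float(np.trapezoid(v, x))
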