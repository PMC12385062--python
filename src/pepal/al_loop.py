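"""Pool-based active-learning orchestration.

The loop follows the classic committee protocol: split the data into
labeled / unlabeled / test partitions, train one model per feature view
on the labeled set, score the pool with the chosen query strategy, reveal
the true labels of the selected batch through a simulated oracle, move
the batch into the labeled set, retrain, and evaluate on the held-out
test partition — until the acquired labels reach a fixed fraction of the
initial pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .committee import (
    BinaryRelevance,
    ViewCommittee,
    default_base_learner,
    ensemble_decide,
    predict_tensor,
    train_committee,
)
from .featurize import ALL_VIEWS, EncoderConfig, FeatureView, build_views, standardize_views
from .io import LabelMatrix, PeptideRecord, ProfilePair
from .metrics import MetricsReport, compute_metrics, curve_area
from .query import QueryBatch, lci_query, mmu_query, qbc_query, random_query

STRATEGIES = ("qbc", "random", "lci", "mmu")


class OracleProtocolError(RuntimeError):
    """Raised when a sample's labels are requested twice."""


@dataclass
class RunConfig:
    """Active-learning run parameters.

    Fractions are taken against the full dataset: 20% test, 4% initially
    labeled, 76% unlabeled pool.  The loop stops once the acquired labels
    reach ``stop_fraction`` of the initial pool; ``lam`` samples are
    queried per iteration (the final batch is truncated, not skipped).
    """

    lam: int = 30
    stop_fraction: float = 0.65
    test_fraction: float = 0.20
    labeled_fraction: float = 0.04
    unlabeled_fraction: float = 0.76
    n_repeats: int = 10
    seed: int = 0
    strategy: str = "qbc"
    view_names: Sequence[str] = ALL_VIEWS

    def __post_init__(self) -> None:
        total = self.test_fraction + self.labeled_fraction + self.unlabeled_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"partition fractions sum to {total}, not 1")
        if not 0 < self.stop_fraction <= 1:
            raise ValueError("stop_fraction must lie in (0, 1]")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class IterationRecord:
    iteration: int
    n_labeled: int
    metrics: MetricsReport
    selected_ids: list[str]
    proportions: np.ndarray  # per-function share of the selected batch

    def to_row(self, label_names: Sequence[str]) -> dict:
        row = {"iteration": self.iteration, "n_labeled": self.n_labeled}
        row.update(self.metrics.as_dict())
        row["selected_ids"] = ";".join(self.selected_ids)
        for name, p in zip(label_names, self.proportions):
            row[f"prop_{name}"] = float(p)
        return row


@dataclass
class ALState:
    """Evolving index partition plus the per-iteration history."""

    labeled_idx: np.ndarray
    unlabeled_idx: np.ndarray
    test_idx: np.ndarray
    iteration: int = 0
    history: list[IterationRecord] = field(default_factory=list)

    def check_invariants(self, n: int) -> None:
        parts = [self.labeled_idx, self.unlabeled_idx, self.test_idx]
        union = np.concatenate(parts)
        if union.size != n or np.unique(union).size != n:
            raise AssertionError("partition is not a disjoint cover")


def split_dataset(
    n: int, config: RunConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded random partition into (labeled, unlabeled, test) indices.

    Sizes are the rounded configured fractions with remainders assigned to
    the unlabeled pool.
    """
    if n < 25:
        raise ValueError("need at least 25 samples for a non-empty partition")
    n_test = round(n * config.test_fraction)
    n_lab = round(n * config.labeled_fraction)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = perm[:n_test]
    labeled = perm[n_test : n_test + n_lab]
    unlabeled = perm[n_test + n_lab :]
    if min(test.size, labeled.size, unlabeled.size) == 0:
        raise ValueError("a partition is empty; adjust fractions or n")
    return labeled, unlabeled, test


def split_kfold(
    n: int, config: RunConfig, seed: int, n_folds: int = 5
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """k-fold test rotation: each fold is the test set once, and the
    remaining samples are split into labeled / unlabeled by the configured
    labeled share of the full dataset."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    out = []
    for k in range(n_folds):
        test = folds[k]
        rest = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        rest = rng.permutation(rest)
        n_lab = round(n * config.labeled_fraction)
        out.append((rest[:n_lab], rest[n_lab:], test))
    return out


class SimulatedOracle:
    """Labeling authority backed by held-out ground truth.

    Each index may be queried exactly once; re-queries are protocol
    errors, mirroring the fact that a wet-lab assay is not repeated for an
    already characterised peptide.
    """

    def __init__(self, ground_truth: LabelMatrix, consumed: Sequence[int] = ()):
        self._truth = ground_truth
        self._consumed: set[int] = set(int(i) for i in consumed)

    def query(self, idx: Sequence[int]) -> np.ndarray:
        idx = [int(i) for i in idx]
        dup = [i for i in idx if i in self._consumed]
        if dup:
            raise OracleProtocolError(f"indices already labeled: {dup[:5]}")
        self._consumed.update(idx)
        return self._truth.values[np.asarray(idx)]


def simulated_oracle(batch: QueryBatch, ground_truth: LabelMatrix) -> np.ndarray:
    """One-shot oracle call for a batch (stateless convenience wrapper)."""
    return ground_truth.values[batch.selected_idx]


def _concat_model_scores(
    views: Sequence[FeatureView],
    labels: LabelMatrix,
    labeled_idx: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and decision values of one binary-relevance model on
    the concatenation of all views (the LCI / MMU substrate)."""
    X = np.hstack([v.matrix for v in views])
    model = BinaryRelevance(default_base_learner, seed=seed).fit(
        X[labeled_idx], labels.values[labeled_idx]
    )
    return model.predict_proba(X), model.decision_values(X)


def run_active_learning(
    records: Sequence[PeptideRecord],
    labels: LabelMatrix,
    profiles: Mapping[str, ProfilePair] | None,
    config: RunConfig,
    encoder_config: EncoderConfig | None = None,
    views: Sequence[FeatureView] | None = None,
) -> tuple[ALState, ViewCommittee]:
    """Execute one full active-learning run.

    Views are encoded once up front (or passed in precomputed, raw and
    unstandardized); only the classifiers retrain per iteration, with
    column standardization refitted on the current labeled rows.  The
    history gains one record per iteration including the iteration-0
    baseline trained on the initial labeled set.
    """
    n = len(records)
    if views is None:
        views = build_views(records, profiles, config.view_names, encoder_config)
    ss = np.random.SeedSequence(config.seed)
    split_seed, model_seed, tie_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    labeled, pool, test = split_dataset(n, config, split_seed)
    state = ALState(labeled_idx=labeled, unlabeled_idx=pool, test_idx=test)
    state.check_invariants(n)
    oracle = SimulatedOracle(labels, consumed=labeled)

    initial_pool = pool.size
    target = int(np.ceil(config.stop_fraction * initial_pool))
    L = labels.n_labels

    def train_and_eval() -> tuple[ViewCommittee, MetricsReport, list[FeatureView]]:
        std = standardize_views(views, state.labeled_idx)
        committee = train_committee(std, labels, state.labeled_idx, model_seed)
        tensor = predict_tensor(committee, std, state.test_idx)
        _, scores = ensemble_decide(tensor)
        report = compute_metrics(scores, labels.values[state.test_idx])
        return committee, report, std

    committee, report, std = train_and_eval()
    state.history.append(
        IterationRecord(0, state.labeled_idx.size, report, [], np.zeros(L))
    )

    acquired = 0
    while acquired < target and state.unlabeled_idx.size:
        lam = min(config.lam, target - acquired, state.unlabeled_idx.size)
        it_seed = int((tie_seed + state.iteration) % (2**31))
        if config.strategy == "qbc":
            tensor = predict_tensor(committee, std, state.unlabeled_idx)
            batch = qbc_query(tensor, state.unlabeled_idx, lam, it_seed)
        elif config.strategy == "random":
            batch = random_query(state.unlabeled_idx, lam, it_seed)
        else:
            probs, decisions = _concat_model_scores(
                std, labels, state.labeled_idx, model_seed
            )
            if config.strategy == "lci":
                batch = lci_query(
                    probs, labels, state.labeled_idx, state.unlabeled_idx,
                    lam, it_seed,
                )
            else:
                batch = mmu_query(decisions, state.unlabeled_idx, lam, it_seed)

        batch_truth = oracle.query(batch.selected_idx)
        state.labeled_idx = np.concatenate([state.labeled_idx, batch.selected_idx])
        mask = ~np.isin(state.unlabeled_idx, batch.selected_idx)
        state.unlabeled_idx = state.unlabeled_idx[mask]
        state.iteration += 1
        acquired += batch.selected_idx.size
        state.check_invariants(n)

        committee, report, std = train_and_eval()
        state.history.append(
            IterationRecord(
                state.iteration,
                state.labeled_idx.size,
                report,
                [records[i].id for i in batch.selected_idx],
                batch_truth.mean(axis=0),
            )
        )
    return state, committee


def balance_statistics(history: Sequence[IterationRecord]) -> np.ndarray:
    """Per-iteration function-coverage proportions of the selected batches.

    Row i gives, for iteration i+1 (the baseline selects nothing), the
    share of that batch positive for each function; multi-label samples
    count toward every function they hold, so rows may sum to > 1.
    """
    if not history:
        raise ValueError("history is empty")
    return np.stack([rec.proportions for rec in history[1:]])


def learning_curve(
    history: Sequence[IterationRecord], metric: str, initial_pool: int
) -> list[tuple[float, float]]:
    """(fraction of training data labeled, metric) points for curve areas."""
    total = history[0].n_labeled + initial_pool
    return [
        (rec.n_labeled / total, getattr(rec.metrics, metric)) for rec in history
    ]


def run_repeats(
    records: Sequence[PeptideRecord],
    labels: LabelMatrix,
    profiles: Mapping[str, ProfilePair] | None,
    config: RunConfig,
    encoder_config: EncoderConfig | None = None,
    views: Sequence[FeatureView] | None = None,
) -> list[ALState]:
    """Independent re-splits: repeat the run with derived seeds."""
    if views is None:
        views = build_views(records, profiles, config.view_names, encoder_config)
    states = []
    for r in range(config.n_repeats):
        cfg = replace(config, seed=int((config.seed + 1000003 * r) % (2**31)))
        state, _ = run_active_learning(
            records, labels, profiles, cfg, encoder_config, views=views
        )
        states.append(state)
    return states
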