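"""Synthetic multifunctional-peptide datasets.

Emulates the statistical shape of the curated therapeutic-peptide corpus
the tool targets: ~4,386 peptides of length 6-200 over the 20 standard
residues, eight function labels with highly sparse assignments (most
samples carry exactly one label; cardinalities 1/2/3 in proportions
4279/90/17) and per-label marginals matching the published category
counts (AIP most frequent, PBP rarest).

Label signal is sequence-statistical, and deliberately heterogeneous
across labels so that different feature views capture different labels —
the committee-diversity premise of multi-view disagreement sampling.  In
the default ``mixed`` mode the eight labels cycle through three signal
channels:

* whole-sequence residue-composition tilt (composition views see it),
* position-restricted composition tilt on the N-terminal half (positional
  views see it well, global composition only in diluted form),
* residue-transition (first-order Markov) tilt with near-base stationary
  composition (pair/order views see it, plain composition barely).

``signal_mode="composition"`` puts every label on the first channel,
which makes the plain composition view the single informative one — the
substrate for per-view quality-ranking checks.  ``signal_strength = 0``
is the null model (sequences carry no label information).  Profiles for
the PSSM/PSFM view are noise-perturbed one-hots — shape- and
scale-correct, not alignment-derived, and therefore synthetic rather
than biological.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import ALPHABET, DEFAULT_LABELS
from .io import (
    LabelMatrix,
    PeptideRecord,
    ProfilePair,
    write_fasta,
    write_label_table,
    write_profile_pair,
)

#: Published per-category sample counts used as default marginal weights.
DEFAULT_LABEL_COUNTS = (135, 981, 367, 1678, 604, 462, 104, 179)

#: Label-combination cardinality counts (1, 2, 3 labels per sample).
DEFAULT_CARDINALITY_COUNTS = (4279, 90, 17)

#: Seed of the fixed per-label signature bank, independent of dataset seed
#: so that label signatures are stable across generated datasets.
_SIGNATURE_SEED = 20250


@dataclass
class SyntheticConfig:
    n_samples: int = 4386
    length_range: tuple[int, int] = (6, 200)
    label_names: tuple[str, ...] = DEFAULT_LABELS
    cardinality_probs: tuple[float, ...] = tuple(
        c / sum(DEFAULT_CARDINALITY_COUNTS) for c in DEFAULT_CARDINALITY_COUNTS
    )
    label_marginals: tuple[float, ...] = tuple(
        c / sum(DEFAULT_LABEL_COUNTS) for c in DEFAULT_LABEL_COUNTS
    )
    signal_strength: float = 0.3
    signal_mode: str = "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cardinality_probs) - 1.0) > 1e-9:
            raise ValueError("cardinality_probs must sum to 1")
        if len(self.label_marginals) != len(self.label_names):
            raise ValueError("one marginal per label required")
        if any(m <= 0 for m in self.label_marginals):
            raise ValueError("label marginals must be positive")
        if len(self.cardinality_probs) > len(self.label_names):
            raise ValueError("max cardinality exceeds number of labels")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.signal_mode not in ("mixed", "composition"):
            raise ValueError("signal_mode must be 'mixed' or 'composition'")
        lo, hi = self.length_range
        if not (6 <= lo <= hi <= 200):
            raise ValueError("length_range must lie within [6, 200]")


def label_signatures(n_labels: int) -> np.ndarray:
    """Fixed (n_labels, 20) bank of residue-preference directions."""
    rng = np.random.default_rng(_SIGNATURE_SEED)
    sig = rng.normal(size=(n_labels, 20))
    return sig / np.linalg.norm(sig, axis=1, keepdims=True) * np.sqrt(20)


def label_transition_signatures(n_labels: int) -> np.ndarray:
    """Fixed (n_labels, 20, 20) bank of residue-transition preferences.

    Rows are centred so the tilt perturbs transition structure while the
    stationary composition stays close to the base composition.
    """
    rng = np.random.default_rng(_SIGNATURE_SEED + 1)
    mats = rng.normal(size=(n_labels, 20, 20))
    mats -= mats.mean(axis=2, keepdims=True)
    return mats


def label_channels(n_labels: int, mode: str) -> list[str]:
    """Which signal channel each label uses (cycled in ``mixed`` mode)."""
    if mode == "composition":
        return ["composition"] * n_labels
    cycle = ("composition", "positional", "transition")
    return [cycle[i % 3] for i in range(n_labels)]


#: Roughly natural residue background (uniform would also do; a mild
#: non-uniform base keeps homopolymer artefacts unlikely).
_BASE_COMPOSITION = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_BASE_COMPOSITION = _BASE_COMPOSITION / _BASE_COMPOSITION.sum()


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    p = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return p / p.sum(axis=-1, keepdims=True)


class _SequenceSampler:
    """Per-label-set sampling distributions, cached across samples.

    For a held label set, the N-terminal half and the C-terminal half each
    get a residue distribution (positional tilts apply to the first half
    only); transition-channel labels additionally contribute a shared
    first-order transition tilt, turning sampling into a Markov chain.
    """

    def __init__(self, config: "SyntheticConfig"):
        L = len(config.label_names)
        self.s = config.signal_strength
        self.channels = label_channels(L, config.signal_mode)
        self.comp_sig = label_signatures(L)
        self.trans_sig = label_transition_signatures(L)
        self.base_log = np.log(_BASE_COMPOSITION)
        self._cache: dict[tuple[int, ...], tuple] = {}

    def _distributions(self, held: tuple[int, ...]):
        if held in self._cache:
            return self._cache[held]
        comp = np.zeros(20)
        pos = np.zeros(20)
        trans = None
        for lab in held:
            ch = self.channels[lab]
            if ch == "composition":
                comp += self.s * self.comp_sig[lab]
            elif ch == "positional":
                pos += self.s * self.comp_sig[lab]
            else:
                trans = (trans if trans is not None else 0) + self.s * self.trans_sig[lab]
        first_logits = self.base_log + comp + pos
        rest_logits = self.base_log + comp
        if trans is None:
            entry = (
                _softmax_rows(first_logits),
                _softmax_rows(rest_logits),
                None,
                None,
            )
        else:
            # cumulative transition rows for fast inverse-CDF stepping
            t_first = _softmax_rows(first_logits[None, :] + trans).cumsum(axis=1)
            t_rest = _softmax_rows(rest_logits[None, :] + trans).cumsum(axis=1)
            entry = (
                _softmax_rows(first_logits),
                _softmax_rows(rest_logits),
                t_first,
                t_rest,
            )
        self._cache[held] = entry
        return entry

    def draw(self, rng: np.random.Generator, length: int, held) -> str:
        p_first, p_rest, t_first, t_rest = self._distributions(
            tuple(sorted(int(h) for h in held))
        )
        half = length // 2
        if t_first is None:
            idx = np.concatenate([
                rng.choice(20, size=half, p=p_first),
                rng.choice(20, size=length - half, p=p_rest),
            ])
        else:
            u = rng.random(length)
            idx = np.empty(length, dtype=int)
            idx[0] = rng.choice(20, p=p_first)
            for i in range(1, length):
                rows = t_first if i < half else t_rest
                idx[i] = np.searchsorted(rows[idx[i - 1]], u[i])
        return "".join(_AA_ARRAY[idx])


_AA_ARRAY = np.array(list(ALPHABET))


def _synthetic_profile(seq: str, rng: np.random.Generator) -> ProfilePair:
    L = len(seq)
    onehot = np.zeros((20, L))
    for i, aa in enumerate(seq):
        onehot[ALPHABET.index(aa), i] = 1.0
    pssm = 8.0 * onehot - 4.0 + rng.normal(0.0, 1.0, size=(20, L))
    raw = 9.0 * onehot + np.abs(rng.normal(0.0, 0.5, size=(20, L))) + 0.05
    psfm = raw / raw.sum(axis=0, keepdims=True)
    return ProfilePair(pssm=pssm, psfm=psfm)


def generate_dataset(
    config: SyntheticConfig, with_profiles: bool = True
) -> tuple[list[PeptideRecord], LabelMatrix, dict[str, ProfilePair]]:
    """Draw a dataset: labels first (cardinality, then that many distinct
    labels proportional to the marginals), then a sequence whose residue
    distribution is tilted by the held labels' signatures.

    Every sample passes the preprocessing filter by construction.
    """
    rng = np.random.default_rng(config.seed)
    L = len(config.label_names)
    sampler = _SequenceSampler(config)
    marg = np.asarray(config.label_marginals)
    marg = marg / marg.sum()
    lo, hi = config.length_range

    records: list[PeptideRecord] = []
    values = np.zeros((config.n_samples, L), dtype=np.int8)
    profiles: dict[str, ProfilePair] = {}
    width = len(str(config.n_samples))
    for i in range(config.n_samples):
        card = rng.choice(len(config.cardinality_probs), p=config.cardinality_probs) + 1
        held = rng.choice(L, size=card, replace=False, p=marg)
        values[i, held] = 1
        length = int(rng.integers(lo, hi + 1))
        seq = sampler.draw(rng, length, held)
        rid = f"syn{i:0{width}d}"
        records.append(PeptideRecord(id=rid, sequence=seq))
        if with_profiles:
            profiles[rid] = _synthetic_profile(seq, rng)
    labels = LabelMatrix(
        list(config.label_names), values, [r.id for r in records]
    )
    return records, labels, profiles


FIXTURE_SIZES = {"tiny": 40, "small": 500, "paper_shape": 4386}


def make_fixture(
    name: str,
    seed: int,
    out_dir: str | Path,
    include_profiles: bool | None = None,
) -> Path:
    """Write a named synthetic dataset to disk.

    ``tiny`` (40 samples) serves unit tests, ``small`` (500) integration
    runs, ``paper_shape`` (4386) full-scale benchmarks.  Output:
    ``peptides.fasta``, ``labels.tsv`` and, when profiles are included
    (default for tiny/small), per-record ``profiles/<id>.pssm`` /
    ``.psfm`` plain tables.
    """
    if name not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture {name!r}; choose from {list(FIXTURE_SIZES)}")
    if include_profiles is None:
        include_profiles = name != "paper_shape"
    config = SyntheticConfig(n_samples=FIXTURE_SIZES[name], seed=seed)
    records, labels, profiles = generate_dataset(config, with_profiles=include_profiles)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out / "peptides.fasta")
    write_label_table(labels, out / "labels.tsv")
    if include_profiles:
        pdir = out / "profiles"
        pdir.mkdir(exist_ok=True)
        for rid, pair in profiles.items():
            write_profile_pair(pair, pdir / f"{rid}.pssm", pdir / f"{rid}.psfm")
    return out
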