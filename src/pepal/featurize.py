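"""Sequence feature views.

Nine encoders turn a peptide into fixed-length numeric vectors:

========  ====  =============================================================
view       dim  description
========  ====  =============================================================
AAC         20  residue frequencies
DPC        400  adjacent ordered-pair frequencies
CTD        273  composition/transition/distribution over 13 attribute splits
PseAAC      25  AAC + 5 sequence-order correlation factors (Chou type 1)
DP         602  reduced-alphabet (14 letters) distance-pair frequencies
DR        1220  residue frequencies + ordered-pair frequencies at distance 1-3
Onehot    4200  200 positions x 21 channels (20 residues + padding)
KSCTriad   343  conjoint-triad (7 classes) triples with gaps k = 0..3
PPCT      2000  PSSM x PSFM cross-transformation, lags 1..5
========  ====  =============================================================

The DP and PPCT recipes are dimension-consistent reconstructions of
descriptors whose operational definitions vary across the literature; see
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .constants import (
    AA_INDEX,
    ALPHABET,
    AMBIGUOUS_RESIDUES,
    CONJOINT_TRIAD_INDEX,
    CTD_GROUPS,
    PSEAAC_PROPERTIES,
    REDUCED_ALPHABET_14,
    REDUCED_INDEX_14,
)
from .io import LabelMatrix, PeptideRecord, ProfilePair

MIN_LENGTH = 6
MAX_LENGTH = 200

#: Fixed output dimensionality of every view.
VIEW_DIMS = {
    "AAC": 20,
    "CTD": 273,
    "DP": 602,
    "DPC": 400,
    "DR": 1220,
    "KSCTriad": 343,
    "Onehot": 4200,
    "PseAAC": 25,
    "PPCT": 2000,
}

ALL_VIEWS = ("AAC", "DPC", "CTD", "PseAAC", "DP", "DR", "Onehot", "KSCTriad", "PPCT")


@dataclass
class EncoderConfig:
    """Tunable encoder parameters (defaults keep the fixed dimensions)."""

    pseaac_lambda: int = 5
    pseaac_weight: float = 0.05
    dp_dr_max_distance: int = 3
    ksctriad_max_gap: int = 3
    onehot_max_len: int = MAX_LENGTH
    ppct_max_lag: int = 5

    def __post_init__(self) -> None:
        if self.pseaac_lambda >= MIN_LENGTH:
            raise ValueError("pseaac_lambda must be < minimum sequence length 6")


@dataclass
class FeatureView:
    """One named encoder's N x d matrix."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = VIEW_DIMS.get(self.name)
        if expected is not None and self.matrix.shape[1] != expected:
            raise ValueError(
                f"view {self.name} has dim {self.matrix.shape[1]}, expected {expected}"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"non-finite entries in view {self.name}")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FilterReport:
    """Removal counts from the preprocessing filter (first matching rule)."""

    n_input: int = 0
    too_short: int = 0
    too_long: int = 0
    nonstandard: int = 0
    no_label: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - (
            self.too_short + self.too_long + self.nonstandard + self.no_label
        )


def preprocess_filter(
    records: Sequence[PeptideRecord], labels: LabelMatrix
) -> tuple[list[PeptideRecord], LabelMatrix, FilterReport]:
    """Apply the dataset preparation rules.

    Retains peptides of length 6-200 composed solely of the 20 standard
    residues and carrying at least one positive function label.  The
    report counts removals by the first matching rule.
    """
    if len(records) != labels.n_samples:
        raise ValueError("records and labels are not row-aligned")
    report = FilterReport(n_input=len(records))
    keep: list[int] = []
    kept_records: list[PeptideRecord] = []
    standard = set(ALPHABET)
    for i, rec in enumerate(records):
        if len(rec) < MIN_LENGTH:
            report.too_short += 1
        elif len(rec) > MAX_LENGTH:
            report.too_long += 1
        elif not set(rec.sequence) <= standard:
            report.nonstandard += 1
        elif labels.values[i].sum() == 0:
            report.no_label += 1
        else:
            keep.append(i)
            kept_records.append(rec)
    return kept_records, labels.subset(keep), report


def _check_standard(seq: str) -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"residues outside the standard alphabet: {sorted(bad)}")


# ---------------------------------------------------------------------------
# composition views
# ---------------------------------------------------------------------------

def encode_aac(seq: str) -> np.ndarray:
    _check_standard(seq)
    v = np.zeros(20)
    for aa in seq:
        v[AA_INDEX[aa]] += 1.0
    return v / len(seq)


def encode_dpc(seq: str) -> np.ndarray:
    _check_standard(seq)
    v = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        v[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1.0
    n_pairs = len(seq) - 1
    return v / n_pairs if n_pairs else v


def encode_ksctriad(seq: str, max_gap: int = 3) -> np.ndarray:
    """Conjoint-triad triples (a, gap k, b, gap k, c), k = 0..max_gap,
    accumulated into one 343-vector and normalized to sum 1."""
    _check_standard(seq)
    cls = [CONJOINT_TRIAD_INDEX[aa] for aa in seq]
    v = np.zeros(343)
    L = len(cls)
    for k in range(max_gap + 1):
        step = k + 1
        for i in range(L - 2 * step):
            v[cls[i] * 49 + cls[i + step] * 7 + cls[i + 2 * step]] += 1.0
    total = v.sum()
    return v / total if total else v


def encode_composition(
    record: PeptideRecord, which: str, config: EncoderConfig | None = None
) -> np.ndarray:
    config = config or EncoderConfig()
    if which == "AAC":
        return encode_aac(record.sequence)
    if which == "DPC":
        return encode_dpc(record.sequence)
    if which == "KSCTriad":
        return encode_ksctriad(record.sequence, config.ksctriad_max_gap)
    raise ValueError(f"unknown composition view {which!r}")


# ---------------------------------------------------------------------------
# physicochemical views
# ---------------------------------------------------------------------------

def encode_ctd(seq: str) -> np.ndarray:
    """273 descriptors: per attribute grouping, 3 class compositions,
    3 class-transition frequencies and 15 distribution positions."""
    _check_standard(seq)
    L = len(seq)
    out = np.empty(0)
    blocks = []
    for groups in CTD_GROUPS.values():
        cls_of = {}
        for ci, grp in enumerate(groups):
            for aa in grp:
                cls_of[aa] = ci
        cls = np.array([cls_of[aa] for aa in seq])
        comp = np.bincount(cls, minlength=3) / L
        trans = np.zeros(3)  # pairs (0,1), (0,2), (1,2) in either order
        pair_slot = {(0, 1): 0, (1, 0): 0, (0, 2): 1, (2, 0): 1, (1, 2): 2, (2, 1): 2}
        for a, b in zip(cls, cls[1:]):
            if a != b:
                trans[pair_slot[(a, b)]] += 1.0
        if L > 1:
            trans /= L - 1
        dist = np.zeros(15)
        for ci in range(3):
            pos = np.flatnonzero(cls == ci) + 1  # 1-based
            if pos.size:
                for qi, q in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
                    k = max(1, math.ceil(q * pos.size))
                    dist[ci * 5 + qi] = pos[k - 1] / L
        blocks.append(np.concatenate([comp, trans, dist]))
    return np.concatenate(blocks)


def encode_pseaac(seq: str, lam: int = 5, weight: float = 0.05) -> np.ndarray:
    """Type-1 pseudo amino-acid composition: 20 frequency terms plus
    ``lam`` sequence-order correlation factors, normalized to sum 1."""
    _check_standard(seq)
    L = len(seq)
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lambda {lam}")
    props = PSEAAC_PROPERTIES[:, [AA_INDEX[aa] for aa in seq]]  # (3, L)
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        diff = props[:, k:] - props[:, :-k]
        theta[k - 1] = np.mean(diff**2)
    freqs = encode_aac(seq)
    denom = 1.0 + weight * theta.sum()
    return np.concatenate([freqs, weight * theta]) / denom


def encode_physchem(
    record: PeptideRecord, which: str, config: EncoderConfig | None = None
) -> np.ndarray:
    config = config or EncoderConfig()
    if which == "CTD":
        return encode_ctd(record.sequence)
    if which == "PseAAC":
        return encode_pseaac(record.sequence, config.pseaac_lambda, config.pseaac_weight)
    raise ValueError(f"unknown physicochemical view {which!r}")


# ---------------------------------------------------------------------------
# distance views
# ---------------------------------------------------------------------------

def _pair_block(idx: Sequence[int], n_symbols: int, delta: int) -> np.ndarray:
    v = np.zeros(n_symbols * n_symbols)
    n = len(idx) - delta
    for i in range(n):
        v[idx[i] * n_symbols + idx[i + delta]] += 1.0
    if n > 0:
        v /= n
    return v


def encode_dr(seq: str, max_distance: int = 3) -> np.ndarray:
    """20 residue frequencies + 400 ordered-pair frequencies for each
    distance delta in 1..max_distance (each block normalized by L-delta)."""
    _check_standard(seq)
    idx = [AA_INDEX[aa] for aa in seq]
    parts = [encode_aac(seq)]
    for delta in range(1, max_distance + 1):
        parts.append(_pair_block(idx, 20, delta))
    return np.concatenate(parts)


def encode_dp(seq: str, max_distance: int = 3) -> np.ndarray:
    """Distance pairs over the 14-letter reduced alphabet: 14 letter
    frequencies + 196 pair frequencies per distance 1..max_distance."""
    _check_standard(seq)
    idx = [REDUCED_INDEX_14[aa] for aa in seq]
    single = np.bincount(idx, minlength=14).astype(float) / len(seq)
    parts = [single]
    for delta in range(1, max_distance + 1):
        parts.append(_pair_block(idx, 14, delta))
    return np.concatenate(parts)


def encode_distance(
    record: PeptideRecord, which: str, config: EncoderConfig | None = None
) -> np.ndarray:
    config = config or EncoderConfig()
    if which == "DR":
        return encode_dr(record.sequence, config.dp_dr_max_distance)
    if which == "DP":
        return encode_dp(record.sequence, config.dp_dr_max_distance)
    raise ValueError(f"unknown distance view {which!r}")


# ---------------------------------------------------------------------------
# one-hot and profile views
# ---------------------------------------------------------------------------

def encode_onehot(
    record: PeptideRecord, config: EncoderConfig | None = None
) -> np.ndarray:
    """Flattened max_len x 21 indicator matrix (20 residues + padding)."""
    config = config or EncoderConfig()
    seq = record.sequence
    _check_standard(seq)
    if len(seq) > config.onehot_max_len:
        raise ValueError(f"sequence longer than {config.onehot_max_len}")
    m = np.zeros((config.onehot_max_len, 21))
    for i, aa in enumerate(seq):
        m[i, AA_INDEX[aa]] = 1.0
    m[len(seq):, 20] = 1.0
    return m.ravel()


def encode_ppct(
    record: PeptideRecord,
    profiles: ProfilePair,
    config: EncoderConfig | None = None,
) -> np.ndarray:
    """PSSM x PSFM cross-transformation.

    PSSM scores are squashed to (0, 1) by a logistic map; for each lag
    g = 1..max_lag and each ordered residue-type pair (u, v) the entry is
    the positional average of pssm[u, i] * psfm[v, i + g].  Lags without
    valid positions contribute zeros.
    """
    config = config or EncoderConfig()
    if profiles.length != len(record):
        raise ValueError("profiles not aligned to record")
    s = expit(profiles.pssm)  # (20, L)
    f = profiles.psfm
    L = profiles.length
    out = np.zeros((config.ppct_max_lag, 20, 20))
    for g in range(1, config.ppct_max_lag + 1):
        if L <= g:
            continue
        out[g - 1] = (s[:, : L - g] @ f[:, g:].T) / (L - g)
    return out.ravel()


# ---------------------------------------------------------------------------
# batch assembly
# ---------------------------------------------------------------------------

def _encode_one(
    rec: PeptideRecord,
    name: str,
    profiles: Mapping[str, ProfilePair] | None,
    config: EncoderConfig,
) -> np.ndarray:
    if name in ("AAC", "DPC", "KSCTriad"):
        return encode_composition(rec, name, config)
    if name in ("CTD", "PseAAC"):
        return encode_physchem(rec, name, config)
    if name in ("DP", "DR"):
        return encode_distance(rec, name, config)
    if name == "Onehot":
        return encode_onehot(rec, config)
    if name == "PPCT":
        return encode_ppct(rec, profiles[rec.id], config)
    raise ValueError(f"unknown view {name!r}")


def build_views(
    records: Sequence[PeptideRecord],
    profiles: Mapping[str, ProfilePair] | None = None,
    view_names: Sequence[str] = ALL_VIEWS,
    config: EncoderConfig | None = None,
    standardize_on: Sequence[int] | None = None,
) -> list[FeatureView]:
    """Encode every record under every requested view.

    When ``standardize_on`` is given, column means and standard deviations
    are fitted on those rows only (the labeled subset) and applied to all
    rows, preventing leakage from the unlabeled pool or test partition.
    """
    config = config or EncoderConfig()
    if "PPCT" in view_names:
        if profiles is None:
            raise ValueError("PPCT view requested but no profiles supplied")
        missing = [r.id for r in records if r.id not in profiles]
        if missing:
            raise ValueError(f"profiles missing for {len(missing)} records")
    views = []
    for name in view_names:
        mat = np.stack([_encode_one(r, name, profiles, config) for r in records])
        views.append(FeatureView(name=name, matrix=mat))
    if standardize_on is not None:
        views = standardize_views(views, standardize_on)
    return views


def standardize_views(
    views: Sequence[FeatureView], fit_idx: Sequence[int]
) -> list[FeatureView]:
    """Column-standardize each view using statistics from ``fit_idx`` rows.

    Constant columns (zero standard deviation) are left centred only.
    """
    fit = np.asarray(fit_idx)
    out = []
    for view in views:
        sub = view.matrix[fit]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        out.append(FeatureView(name=view.name, matrix=(view.matrix - mean) / sd))
    return out
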