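"""Reading and writing the plain-text formats the tool touches.

FASTA peptide files, delimited binary label tables, PSSM/PSFM profile
files (PSI-BLAST ASCII dialect or plain numeric tables) and per-iteration
active-learning history tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import DEFAULT_LABELS, PSIBLAST_TO_ALPHA


class EmptyInputError(ValueError):
    """Raised when an input file contains no usable records."""


class DuplicateIdError(ValueError):
    """Raised when two records in one dataset share an identifier."""


class ProfileAlignmentError(ValueError):
    """Raised when a profile's length disagrees with its peptide."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: identifier plus upper-case amino-acid sequence.

    The parser accepts any alphabetic sequence; restriction to the 20
    standard residues (and the 6-200 length window) is the preprocessing
    filter's job, so that removals can be counted and reported.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid peptide id: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabelMatrix:
    """N x L binary function annotations, row-aligned with a peptide list."""

    labels: list[str]
    values: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("label matrix shape disagrees with label names")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label matrix entries must be 0 or 1")
        if self.ids is not None and len(self.ids) != self.values.shape[0]:
            raise ValueError("id list length disagrees with matrix rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_labels(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: Sequence[int]) -> "LabelMatrix":
        ids = [self.ids[i] for i in idx] if self.ids is not None else None
        return LabelMatrix(
            list(self.labels), self.values[np.asarray(idx, dtype=int)], ids
        )


@dataclass
class ProfilePair:
    """Position-specific scoring and frequency matrices for one peptide.

    Both matrices are oriented 20 x L (residue rows in alphabetical order,
    one column per sequence position); PSFM columns sum to one.
    """

    pssm: np.ndarray
    psfm: np.ndarray

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.psfm = np.asarray(self.psfm, dtype=float)
        if self.pssm.shape != self.psfm.shape or self.pssm.shape[0] != 20:
            raise ValueError("profile matrices must both be 20 x L")

    @property
    def length(self) -> int:
        return self.pssm.shape[1]


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Parse a FASTA file into :class:`PeptideRecord` objects.

    Sequences are upper-cased and wrapped lines concatenated; the header
    text up to the first whitespace becomes the id.  Non-alphabetic
    characters in a sequence are a parse error; ambiguous residue codes
    pass (the preprocessing filter owns that rule).
    """
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise EmptyInputError(f"record {rec.id} has an empty sequence")
        if not (seq.isascii() and seq.isalpha()):
            raise ValueError(f"non-alphabetic characters in sequence {rec.id}")
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(PeptideRecord(id=rec.id, sequence=seq))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_label_table(
    path: str | Path,
    label_names: Sequence[str] = DEFAULT_LABELS,
) -> LabelMatrix:
    """Read a delimited (tab or comma, auto-detected) binary label table.

    The first column (or a column named ``id``) carries sample ids; the
    requested label columns are returned in the requested order.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise EmptyInputError(f"empty label table {path}")
    id_col = "id" if "id" in df.columns else df.columns[0]
    missing = [name for name in label_names if name not in df.columns]
    if missing:
        raise KeyError(f"label columns missing from {path}: {missing}")
    values = df[list(label_names)].to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("label table cells must be 0 or 1")
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate ids in label table")
    return LabelMatrix(list(label_names), values, ids)


def write_label_table(
    labels: LabelMatrix, path: str | Path, id_col: str = "id"
) -> None:
    if labels.ids is None:
        raise ValueError("label matrix has no ids to write")
    df = pd.DataFrame(labels.values, columns=labels.labels)
    df.insert(0, id_col, labels.ids)
    df.to_csv(path, sep="\t", index=False)


def _looks_like_psiblast(lines: list[str]) -> bool:
    for line in lines[:5]:
        tokens = line.split()
        if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
            return True
    return False


def _parse_psiblast_ascii(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Returns (scores, percents) as L x 20 arrays in alphabetical residue
    order; percents is ``None`` when the file carries only the score block.
    """
    scores, percents = [], []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if len(tokens) < 22 or not tokens[0].isdigit():
                continue
            if len(tokens[1]) != 1 or not tokens[1].isalpha():
                continue
            row = [float(t) for t in tokens[2:22]]
            scores.append(row)
            if len(tokens) >= 42:
                percents.append([float(t) for t in tokens[22:42]])
    if not scores:
        raise ValueError(f"no matrix rows found in {path}")
    s = np.array(scores)[:, PSIBLAST_TO_ALPHA]
    p = None
    if len(percents) == len(scores):
        p = np.array(percents)[:, PSIBLAST_TO_ALPHA]
    return s, p


def _read_profile_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    with open(path) as fh:
        head = [next(fh, "") for _ in range(5)]
    if _looks_like_psiblast(head):
        return _parse_psiblast_ascii(path)
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[1] != 20:
        raise ValueError(f"profile table {path} must have 20 columns")
    return mat, None


def read_profile_pair(
    pssm_path: str | Path,
    psfm_path: str | Path | None,
    record: PeptideRecord,
    psfm_from_pssm_file: bool = False,
) -> ProfilePair:
    """Read a PSSM/PSFM pair for one peptide.

    ``pssm_path`` may be a PSI-BLAST ASCII matrix or a plain L x 20 table.
    The PSFM comes either from ``psfm_path`` (plain table of frequencies)
    or, with ``psfm_from_pssm_file``, from the percentage block of the
    PSI-BLAST file (divided by 100).  Per-position frequency columns that
    do not sum to 1 within 1e-6 trigger a warning and are renormalized.
    """
    scores, percents = _read_profile_matrix(pssm_path)
    if scores.shape[0] != len(record):
        raise ProfileAlignmentError(
            f"PSSM length {scores.shape[0]} != sequence length {len(record)}"
            f" for {record.id}"
        )
    if psfm_from_pssm_file:
        if percents is None:
            raise ValueError("PSSM file carries no frequency block")
        freq = percents / 100.0
    else:
        if psfm_path is None:
            raise ValueError("psfm_path required unless psfm_from_pssm_file")
        freq, _ = _read_profile_matrix(psfm_path)
    if freq.shape[0] != len(record):
        raise ProfileAlignmentError(
            f"PSFM length {freq.shape[0]} != sequence length {len(record)}"
            f" for {record.id}"
        )
    sums = freq.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        warnings.warn(
            f"PSFM rows for {record.id} do not sum to 1; renormalizing",
            stacklevel=2,
        )
        safe = np.where(sums > 0, sums, 1.0)
        freq = freq / safe[:, None]
    return ProfilePair(pssm=scores.T, psfm=freq.T)


def write_profile_pair(
    pair: ProfilePair, pssm_path: str | Path, psfm_path: str | Path
) -> None:
    """Write a profile pair as plain L x 20 numeric tables."""
    np.savetxt(pssm_path, pair.pssm.T, fmt="%.6f")
    np.savetxt(psfm_path, pair.psfm.T, fmt="%.8f")


METRIC_COLUMNS = ("macro_auc", "micro_auc", "aps", "one_error", "ranking_loss")


def write_history(
    state_history: Iterable[Mapping | object],
    path: str | Path,
    label_names: Sequence[str] = DEFAULT_LABELS,
) -> None:
    """Write per-iteration active-learning records as a TSV table.

    Accepts mappings or objects exposing ``to_row(label_names)``.  Columns:
    iteration, n_labeled, the five metrics, selected_ids (semicolon
    joined), then one selection-proportion column per function label.
    """
    rows = []
    for rec in state_history:
        if hasattr(rec, "to_row"):
            rows.append(rec.to_row(label_names))
        else:
            rows.append(dict(rec))
    columns = (
        ["iteration", "n_labeled", *METRIC_COLUMNS, "selected_ids"]
        + [f"prop_{name}" for name in label_names]
    )
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_history(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
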