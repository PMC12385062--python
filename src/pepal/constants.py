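"""Amino-acid constants shared by the feature encoders.

All residue-indexed arrays use the alphabetical ordering of the 20
standard one-letter codes (``ALPHABET``).  The grouping tables below are
standard published scales; each three-way grouping partitions the 20
residues exactly (asserted at import time).
"""

from __future__ import annotations

import numpy as np

#: The 20 standard residues, alphabetical.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residue -> column index in every 20-wide encoding.
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Ambiguity / non-standard codes that are parse-legal but rejected by the
#: dataset preprocessing filter.
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")

# ---------------------------------------------------------------------------
# Composition / transition / distribution groupings.
#
# Thirteen physicochemical attributes, each splitting the residues into three
# classes: seven hydrophobicity scales plus normalized van der Waals volume,
# polarity, polarizability, charge, secondary structure and solvent
# accessibility.  Each attribute contributes 3 composition + 3 transition +
# 15 distribution descriptors = 21, for 13 * 21 = 273 total.
# ---------------------------------------------------------------------------
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

for _name, _groups in CTD_GROUPS.items():
    assert sorted("".join(_groups)) == sorted(ALPHABET), _name

# ---------------------------------------------------------------------------
# Conjoint-triad classes: residues clustered by dipole and side-chain volume
# into seven classes, giving 7**3 = 343 triad types.
# ---------------------------------------------------------------------------
CONJOINT_TRIAD_CLASSES: tuple[str, ...] = (
    "AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C",
)
CONJOINT_TRIAD_INDEX = {
    aa: ci for ci, cls in enumerate(CONJOINT_TRIAD_CLASSES) for aa in cls
}
assert len(CONJOINT_TRIAD_INDEX) == 20

# ---------------------------------------------------------------------------
# 14-letter reduced alphabet for the distance-pair view: chemically similar
# pairs (D/E, F/Y, I/V, K/R, L/M, S/T) are merged, the rest stay singletons.
# 14 single-letter frequencies + 3 * 14^2 pair frequencies = 602.
# ---------------------------------------------------------------------------
REDUCED_ALPHABET_14: tuple[str, ...] = (
    "A", "C", "DE", "FY", "G", "H", "IV", "KR", "LM", "N", "P", "Q", "ST", "W",
)
REDUCED_INDEX_14 = {
    aa: gi for gi, grp in enumerate(REDUCED_ALPHABET_14) for aa in grp
}
assert len(REDUCED_INDEX_14) == 20

# ---------------------------------------------------------------------------
# Physicochemical property scales used by the pseudo amino-acid composition
# correlation factors: hydrophobicity, hydrophilicity, side-chain mass.
# Values are the classical published scales; they are standardised to zero
# mean / unit variance over the 20 residues before use.
# ---------------------------------------------------------------------------
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardised(table: dict[str, float]) -> np.ndarray:
    v = np.array([table[aa] for aa in ALPHABET], dtype=float)
    return (v - v.mean()) / v.std()


#: (3, 20) array: standardised hydrophobicity / hydrophilicity / mass rows.
PSEAAC_PROPERTIES = np.vstack(
    [
        _standardised(_HYDROPHOBICITY),
        _standardised(_HYDROPHILICITY),
        _standardised(_SIDE_CHAIN_MASS),
    ]
)

#: PSI-BLAST ASCII matrix column order (differs from alphabetical).
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"
PSIBLAST_TO_ALPHA = np.array(
    [PSIBLAST_COLUMN_ORDER.index(aa) for aa in ALPHABET]
)

#: Default function-label names, fixed column order.
DEFAULT_LABELS = ("AAP", "ABP", "ACP", "AIP", "AVP", "CPP", "PBP", "QSP")
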