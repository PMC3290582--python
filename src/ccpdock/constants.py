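"""Shared chemical tables: residue alphabets, charges, side-chain extents,
groove-edge atom sets and the canonical interaction-key orderings.

The coarse-grained model represents every amino acid by one pseudo-atom at
its C-beta and every nucleotide by three interacting centers: the phosphate
(P), a major-groove face (M) and a minor-groove face (m).  The interaction
key spaces defined here — 20 amino acids x 5 bases x 3 moieties = 300 full
keys, and 20 x 3 = 60 nucleotide-independent reduced keys — are fixed and
ordered so that profile vectors from different poses are always comparable.
"""

from __future__ import annotations

# 20 standard amino acids, three-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

AA_ONE_TO_THREE: dict[str, str] = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_THREE_TO_ONE: dict[str, str] = {v: k for k, v in AA_ONE_TO_THREE.items()}

# Canonical base ordering for profile keys.
BASES: tuple[str, ...] = ("A", "C", "G", "U", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

# Canonical moiety ordering: major groove, minor groove, phosphate.
MOIETIES: tuple[str, ...] = ("M", "m", "P")
MOIETY_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOIETIES)}

# Full 300-key interaction space, ordered aa (alphabetical) x base x moiety.
CCP_KEYS: tuple[tuple[str, str, str], ...] = tuple(
    (aa, b, m) for aa in AMINO_ACIDS for b in BASES for m in MOIETIES
)
CCP_KEY_INDEX: dict[tuple[str, str, str], int] = {k: i for i, k in enumerate(CCP_KEYS)}

# Nucleotide-independent reduced space: (amino acid, moiety), 60 keys.
REDUCED_KEYS: tuple[tuple[str, str], ...] = tuple(
    (aa, m) for aa in AMINO_ACIDS for m in MOIETIES
)
REDUCED_KEY_INDEX: dict[tuple[str, str], int] = {k: i for i, k in enumerate(REDUCED_KEYS)}

# Formal side-chain charges at neutral pH.  Histidine defaults to neutral
# but is configurable in structures.protein_sites.
RESIDUE_CHARGES: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
RESIDUE_CHARGES.update({"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1})

# Default average side-chain extent <e> beyond C-beta, in Angstroms.
# Computed from idealized extended side-chain geometry (C-beta to the most
# distal heavy atom) plus a 0.5 A pad; glycine is pinned to 0 because its
# site sits on C-alpha.  Fully overridable via the extent_table argument of
# structures.protein_sites.
DEFAULT_EXTENTS: dict[str, float] = {
    "ALA": 0.5, "ARG": 6.7, "ASN": 2.9, "ASP": 2.9, "CYS": 2.3,
    "GLN": 4.1, "GLU": 4.2, "GLY": 0.0, "HIS": 4.0, "ILE": 3.1,
    "LEU": 3.1, "LYS": 5.5, "MET": 4.6, "PHE": 4.6, "PRO": 2.0,
    "SER": 1.9, "THR": 1.9, "TRP": 5.5, "TYR": 6.1, "VAL": 2.0,
}

# Residue-name aliases accepted for nucleotides (modern DNA names, legacy
# one-letter names, and RNA names), mapped to the base letter.
NUCLEOTIDE_NAMES: dict[str, str] = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
}

# Groove-edge heavy atoms whose centroid defines each groove center.  These
# are the base-edge atoms facing the respective groove in a Watson-Crick
# pair; the placement is an explicit approximation (see docs) and both sets
# are overridable via the groove_atoms argument of structures.na_sites.
MAJOR_GROOVE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N6", "N7", "C5"),
    "G": ("O6", "N7", "C5"),
    "C": ("N4", "C5", "C6"),
    "T": ("O4", "C5", "C6"),
    "U": ("O4", "C5", "C6"),
}
MINOR_GROOVE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("C2", "N3"),
    "G": ("N2", "N3", "C2"),
    "C": ("O2", "C2"),
    "T": ("O2", "C2"),
    "U": ("O2", "C2"),
}

# EMBOSS-style pKa values used by train.isoelectric_point; overridable.
DEFAULT_PKA: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
POSITIVE_PKA_GROUPS: tuple[str, ...] = ("K", "R", "H")
NEGATIVE_PKA_GROUPS: tuple[str, ...] = ("D", "E", "C", "Y")
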