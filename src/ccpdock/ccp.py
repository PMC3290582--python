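"""Chemical Context Profile (CCP) and Chemical Context Discrepancy (CCD).

The CCP of a docking pose is a 300-dimensional nonnegative vector indexed by
(amino acid, base, moiety), where moiety is one of the three nucleotide
interacting centers (P phosphate, M major groove, m minor groove).  Each
entry accumulates the pair energy

    f(r) = 1 / max(3.5, r - <e>)

over every (residue, nucleotide) pair of that interaction type, where r is
the separation between the residue's C-beta pseudo-atom and the nucleotide
center, and <e> is the residue's average side-chain extent.  Within the
extent the interaction plateaus at 1/3.5; beyond it, it decays as 1/r like a
screened electrostatic potential.  A residue interacts with the phosphate of
every nucleotide but with only the nearer of the two grooves.

The CCD between two poses of the same complex is the angle between their
CCP vectors — a chemistry-based stand-in for RMSD that is insensitive to
the rotational/translational degeneracy of helical (especially palindromic)
DNA.  Note that the angle is zero for *proportional* vectors, not only
identical ones; in practice the triangulation of many centers makes
proportional-but-different poses essentially impossible.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    AA_INDEX,
    AMINO_ACIDS,
    BASE_INDEX,
    BASES,
    CCP_KEY_INDEX,
    CCP_KEYS,
    MOIETIES,
    MOIETY_INDEX,
    REDUCED_KEYS,
)
from .errors import EmptyInterfaceError

__all__ = [
    "CCPVector",
    "ReducedCCP",
    "GroupingScheme",
    "pair_energy",
    "closest_groove",
    "ccp_vector",
    "ccp_magnitude",
    "ccd",
    "compress_ccp",
    "identity_scheme",
    "nucleotide_independent_scheme",
    "six_class_scheme",
]

PLATEAU = 3.5  # A; floor of the effective separation in f(r)


def pair_energy(r, extent) -> np.ndarray | float:
    """Pair energy f(r) = 1/max(3.5, r - <e>); vectorized over r and extent."""
    r = np.asarray(r, dtype=float)
    e = np.asarray(extent, dtype=float)
    if np.any(r < 0) or np.any(e < 0):
        raise ValueError("separation and extent must be nonnegative")
    out = 1.0 / np.maximum(PLATEAU, r - e)
    return float(out) if out.ndim == 0 else out


class CCPVector:
    """The 300-entry interaction profile with a fixed canonical key order."""

    __slots__ = ("values",)

    keys = CCP_KEYS
    key_index = CCP_KEY_INDEX

    def __init__(self, values: Optional[np.ndarray] = None):
        if values is None:
            self.values = np.zeros(len(CCP_KEYS))
        else:
            values = np.asarray(values, dtype=float).reshape(-1)
            if values.shape != (len(CCP_KEYS),):
                raise ValueError(f"CCP vector needs {len(CCP_KEYS)} entries")
            if np.any(values < 0):
                raise ValueError("CCP entries must be nonnegative")
            self.values = values.copy()

    def __getitem__(self, key: tuple[str, str, str]) -> float:
        return float(self.values[CCP_KEY_INDEX[key]])

    def __len__(self) -> int:
        return len(CCP_KEYS)

    def magnitude(self) -> float:
        return float(np.linalg.norm(self.values))

    def as_dict(self) -> dict[tuple[str, str, str], float]:
        return {k: float(v) for k, v in zip(CCP_KEYS, self.values)}

    def as_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(CCP_KEYS, names=["aa", "base", "moiety"])
        return pd.Series(self.values, index=idx, name="value")

    # -- serialization ----------------------------------------------------
    def to_tsv(self) -> str:
        df = pd.DataFrame(CCP_KEYS, columns=["aa", "base", "moiety"])
        df["value"] = self.values
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "CCPVector":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        vec = np.zeros(len(CCP_KEYS))
        for _, row in df.iterrows():
            vec[CCP_KEY_INDEX[(row["aa"], row["base"], row["moiety"])]] = row["value"]
        return cls(vec)

    def to_json(self) -> str:
        return json.dumps({"|".join(k): v for k, v in self.as_dict().items()})

    @classmethod
    def from_json(cls, text: str) -> "CCPVector":
        data = json.loads(text)
        vec = np.zeros(len(CCP_KEYS))
        for key, v in data.items():
            aa, base, moiety = key.split("|")
            vec[CCP_KEY_INDEX[(aa, base, moiety)]] = v
        return cls(vec)


@dataclass(eq=False)
class GroupingScheme:
    """A named partition of the 300 full keys into reduced keys."""

    name: str
    mapping: Mapping[tuple[str, str, str], tuple]

    def __post_init__(self) -> None:
        missing = set(CCP_KEYS) - set(self.mapping)
        extra = set(self.mapping) - set(CCP_KEYS)
        if missing or extra:
            raise ValueError(
                f"grouping scheme {self.name!r} is not a partition of the key space "
                f"({len(missing)} missing, {len(extra)} extra keys)"
            )

    @property
    def reduced_keys(self) -> list[tuple]:
        seen: list[tuple] = []
        for k in CCP_KEYS:
            rk = self.mapping[k]
            if rk not in seen:
                seen.append(rk)
        return seen


@dataclass(eq=False)
class ReducedCCP:
    """A grouped (compressed) profile; entry sums are conserved."""

    grouping_scheme: str
    entries: dict

    def total(self) -> float:
        return float(sum(self.entries.values()))


def identity_scheme() -> GroupingScheme:
    return GroupingScheme("identity", {k: k for k in CCP_KEYS})


def nucleotide_independent_scheme() -> GroupingScheme:
    """Collapse the base axis: 20 amino acids x 3 moieties = 60 keys."""
    return GroupingScheme(
        "nucleotide_independent", {(aa, b, m): (aa, m) for (aa, b, m) in CCP_KEYS}
    )


_SIX_CLASSES: dict[str, str] = {}
for _cls, _members in {
    "aliphatic": ("ALA", "VAL", "LEU", "ILE", "MET"),
    "aromatic": ("PHE", "TRP", "TYR"),
    "polar": ("SER", "THR", "ASN", "GLN", "CYS"),
    "positive": ("LYS", "ARG", "HIS"),
    "negative": ("ASP", "GLU"),
    "special": ("GLY", "PRO"),
}.items():
    for _aa in _members:
        _SIX_CLASSES[_aa] = _cls


def six_class_scheme() -> GroupingScheme:
    """Six amino-acid classes x 3 moieties = 18 keys (base-independent)."""
    return GroupingScheme(
        "six_class", {(aa, b, m): (_SIX_CLASSES[aa], m) for (aa, b, m) in CCP_KEYS}
    )


def closest_groove(site, nuc) -> str:
    """Return the groove ('M' or 'm') whose center is nearer the site's
    C-beta position; exact ties resolve to the major groove."""
    d_major = np.linalg.norm(site.position - nuc.major_position)
    d_minor = np.linalg.norm(site.position - nuc.minor_position)
    return "M" if d_major <= d_minor else "m"


def ccp_vector(
    protein_sites: Sequence,
    na_sites: Sequence,
    cutoff: Optional[float] = None,
    radial: Optional[Callable] = None,
) -> CCPVector:
    """Accumulate the Chemical Context Profile over all site/nucleotide pairs.

    Every pair contributes f(r) to its (aa, base, P) entry via the phosphate
    center (when present) and to exactly one of (aa, base, M) / (aa, base, m)
    per the closest-groove rule.  ``cutoff`` (default None = exact behaviour)
    drops pairs beyond that separation for performance only.  ``radial``
    replaces f(r, extent) with an alternative radial form.
    """
    if not len(protein_sites) or not len(na_sites):
        raise EmptyInterfaceError("CCP requires at least one site on each molecule")
    f = radial if radial is not None else pair_energy
    pos = np.array([s.position for s in protein_sites])
    ext = np.array([s.extent for s in protein_sites])
    aa_idx = np.array([AA_INDEX[s.residue_type] for s in protein_sites])
    grid = np.zeros((len(AMINO_ACIDS), len(BASES), len(MOIETIES)))
    i_M, i_m, i_P = MOIETY_INDEX["M"], MOIETY_INDEX["m"], MOIETY_INDEX["P"]
    for nuc in na_sites:
        b = BASE_INDEX[nuc.base_type]
        d_major = np.linalg.norm(pos - nuc.major_position, axis=1)
        d_minor = np.linalg.norm(pos - nuc.minor_position, axis=1)
        use_major = d_major <= d_minor
        d_groove = np.where(use_major, d_major, d_minor)
        fg = f(d_groove, ext)
        if cutoff is not None:
            fg = np.where(d_groove <= cutoff, fg, 0.0)
        np.add.at(grid[:, b, i_M], aa_idx[use_major], fg[use_major])
        np.add.at(grid[:, b, i_m], aa_idx[~use_major], fg[~use_major])
        if nuc.p_position is not None:
            d_p = np.linalg.norm(pos - nuc.p_position, axis=1)
            fp = f(d_p, ext)
            if cutoff is not None:
                fp = np.where(d_p <= cutoff, fp, 0.0)
            np.add.at(grid[:, b, i_P], aa_idx, fp)
    return CCPVector(grid.reshape(-1))


def ccp_magnitude(v: CCPVector) -> float:
    """Euclidean norm of the 300 profile entries (|CCP|)."""
    return v.magnitude()


def ccd(native: CCPVector, model: CCPVector) -> float:
    """Chemical Context Discrepancy: angle between two profiles, in degrees.

    Entries are nonnegative, so the angle lies in [0, 90] degrees.  Raises
    :class:`EmptyInterfaceError` if either profile has zero magnitude.
    """
    na, nm = native.magnitude(), model.magnitude()
    if na == 0.0 or nm == 0.0:
        raise EmptyInterfaceError("CCD undefined for an empty interface (|CCP| = 0)")
    cosang = float(np.dot(native.values, model.values)) / (na * nm)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def compress_ccp(v: CCPVector, scheme: GroupingScheme) -> ReducedCCP:
    """Sum profile entries within each group of a partition scheme."""
    entries: dict = {rk: 0.0 for rk in scheme.reduced_keys}
    for k, val in zip(CCP_KEYS, v.values):
        entries[scheme.mapping[k]] += float(val)
    return ReducedCCP(grouping_scheme=scheme.name, entries=entries)


def reduced_profile_array(v: CCPVector) -> np.ndarray:
    """Nucleotide-independent 60-vector in canonical (aa, moiety) order."""
    grid = v.values.reshape(len(AMINO_ACIDS), len(BASES), len(MOIETIES))
    return grid.sum(axis=1).reshape(-1)


# canonical ordering of the reduced feature space, re-exported for training
REDUCED_FEATURES = REDUCED_KEYS
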