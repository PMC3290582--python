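"""PDB parsing and reduction to the coarse-grained pseudo-atom representation.

A protein chain becomes one :class:`ProteinSite` per residue, centered on the
C-beta atom (C-alpha for glycine), annotated with the residue's average
side-chain extent and formal charge.  A nucleic-acid chain becomes one
:class:`NucleotideSites` per nucleotide carrying three interacting centers:
the phosphorus position (absent at the 5' terminus) and the centroids of the
major- and minor-groove base-edge atoms.

PDB reading/writing is delegated to :mod:`gemmi`; this module only performs
the coordinate-field validation and the pseudo-atom reduction.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .constants import (
    AMINO_ACIDS,
    DEFAULT_EXTENTS,
    MAJOR_GROOVE_ATOMS,
    MINOR_GROOVE_ATOMS,
    NUCLEOTIDE_NAMES,
    RESIDUE_CHARGES,
)
from .errors import PDBParseError

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ProteinSite",
    "NucleotideSites",
    "ComplexPose",
    "parse_structure",
    "protein_sites",
    "na_sites",
    "write_pdb",
    "sites_to_tsv",
]


@dataclass(eq=False)
class AtomRecord:
    """One ATOM/HETATM record reduced to the fields the package uses."""

    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise PDBParseError(
                f"atom {self.atom_name} in {self.residue_name} {self.residue_index}: "
                "position must be a finite 3-vector"
            )


@dataclass(eq=False)
class ProteinSite:
    """Single-pseudo-atom residue: C-beta position, extent and charge."""

    residue_type: str
    chain_id: str
    residue_index: int
    position: np.ndarray
    extent: float
    charge: int
    ca_position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.ca_position is not None:
            self.ca_position = np.asarray(self.ca_position, dtype=float)
        if self.extent < 0:
            raise ValueError("side-chain extent must be nonnegative")
        if self.charge not in (-1, 0, 1):
            raise ValueError("charge must be -1, 0 or +1")
        if self.charge == -1 and self.residue_type not in ("ASP", "GLU"):
            raise ValueError(f"negative charge invalid for {self.residue_type}")
        if self.charge == +1 and self.residue_type not in ("LYS", "ARG", "HIS"):
            raise ValueError(f"positive charge invalid for {self.residue_type}")


@dataclass(eq=False)
class NucleotideSites:
    """Per-nucleotide interacting centers: phosphate, major and minor groove.

    ``c2p_position`` and ``c4_position`` (sugar C2' and base C4) are kept when
    available because DNA RMSD is measured over P, C2' and C4.
    """

    base_type: str
    chain_id: str
    residue_index: int
    major_position: np.ndarray
    minor_position: np.ndarray
    p_position: Optional[np.ndarray] = None
    c2p_position: Optional[np.ndarray] = None
    c4_position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.major_position = np.asarray(self.major_position, dtype=float)
        self.minor_position = np.asarray(self.minor_position, dtype=float)
        for name in ("p_position", "c2p_position", "c4_position"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if np.allclose(self.major_position, self.minor_position):
            raise ValueError("major and minor groove centers must differ")


@dataclass(eq=False)
class ComplexPose:
    """One rigid placement of a DNA relative to a protein."""

    protein_sites: list
    na_sites: list
    pose_id: str = "pose"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein_sites or not self.na_sites:
            raise ValueError("a pose needs at least one protein site and one nucleotide")


def _validate_coordinates(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                ) from None


def parse_structure(pdb_text: str) -> dict[str, list[AtomRecord]]:
    """Parse PDB text into atom records grouped by chain id.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first encountered).  Raises :class:`PDBParseError` on
    empty input, absence of ATOM/HETATM records, or a malformed coordinate
    field (the error names the offending line).
    """
    if not pdb_text or not pdb_text.strip():
        raise PDBParseError("empty PDB input")
    _validate_coordinates(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise PDBParseError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no models in PDB input")
    model = st[0]
    chains: dict[str, list[AtomRecord]] = {}
    for chain in model:
        records: list[AtomRecord] = []
        for res in chain:
            # resolve altlocs per atom name: highest occupancy, ties first
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in res:  # preserve file order of the winners
                if best.get(atom.name) is atom:
                    records.append(
                        AtomRecord(
                            atom_name=atom.name,
                            element=atom.element.name,
                            residue_name=res.name.strip(),
                            residue_index=res.seqid.num,
                            chain_id=chain.name,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            insertion_code=(res.seqid.icode or "").strip(),
                        )
                    )
        if records:
            chains[chain.name] = records
    if not chains:
        raise PDBParseError("no ATOM records found")
    return chains


def _group_residues(
    atoms: Iterable[AtomRecord],
) -> list[tuple[tuple[str, int, str], str, dict[str, np.ndarray]]]:
    """Group atoms into residues, preserving encounter (file) order."""
    order: list[tuple[str, int, str]] = []
    names: dict[tuple[str, int, str], str] = {}
    coords: dict[tuple[str, int, str], dict[str, np.ndarray]] = {}
    for a in atoms:
        key = (a.chain_id, a.residue_index, a.insertion_code)
        if key not in coords:
            order.append(key)
            coords[key] = {}
            names[key] = a.residue_name
        coords[key].setdefault(a.atom_name, a.position)
    return [(k, names[k], coords[k]) for k in order]


def protein_sites(
    atoms: Sequence[AtomRecord],
    extent_table: Optional[Mapping[str, float]] = None,
    histidine_charge: int = 0,
) -> list[ProteinSite]:
    """Reduce amino-acid residues to one pseudo-atom each at the C-beta.

    Glycine (no C-beta) uses the C-alpha position with extent 0.  Residues
    missing both C-beta and C-alpha, or with unknown names, are skipped with
    a logged warning.
    """
    extents = dict(DEFAULT_EXTENTS)
    if extent_table:
        extents.update(extent_table)
    charges = dict(RESIDUE_CHARGES)
    charges["HIS"] = histidine_charge
    sites: list[ProteinSite] = []
    for (chain_id, idx, _icode), resname, coords in _group_residues(atoms):
        if resname not in AMINO_ACIDS:
            logger.warning("skipping unknown residue %s %s:%d", resname, chain_id, idx)
            continue
        cb = coords.get("CB")
        ca = coords.get("CA")
        if resname == "GLY" or cb is None:
            pos = ca
            extent = 0.0 if cb is None else extents[resname]
        else:
            pos = cb
            extent = extents[resname]
        if pos is None:
            logger.warning(
                "skipping residue %s %s:%d with no CB or CA atom", resname, chain_id, idx
            )
            continue
        sites.append(
            ProteinSite(
                residue_type=resname,
                chain_id=chain_id,
                residue_index=idx,
                position=pos,
                extent=extent,
                charge=charges[resname],
                ca_position=ca,
            )
        )
    return sites


def na_sites(
    atoms: Sequence[AtomRecord],
    major_groove_atoms: Optional[Mapping[str, tuple[str, ...]]] = None,
    minor_groove_atoms: Optional[Mapping[str, tuple[str, ...]]] = None,
) -> list[NucleotideSites]:
    """Reduce nucleotides to their three interacting centers.

    The phosphate center sits on the phosphorus atom (absent for a
    5'-terminal nucleotide); the groove centers are centroids of the
    groove-edge base atoms.  Nucleotides missing either groove-edge atom set
    are skipped with a warning.
    """
    major_tab = dict(MAJOR_GROOVE_ATOMS)
    minor_tab = dict(MINOR_GROOVE_ATOMS)
    if major_groove_atoms:
        major_tab.update(major_groove_atoms)
    if minor_groove_atoms:
        minor_tab.update(minor_groove_atoms)
    out: list[NucleotideSites] = []
    for (chain_id, idx, _icode), resname, coords in _group_residues(atoms):
        base = NUCLEOTIDE_NAMES.get(resname)
        if base is None:
            logger.warning("skipping unknown nucleotide %s %s:%d", resname, chain_id, idx)
            continue
        maj = [coords[n] for n in major_tab[base] if n in coords]
        mino = [coords[n] for n in minor_tab[base] if n in coords]
        if not maj or not mino:
            logger.warning(
                "skipping nucleotide %s %s:%d with no groove-edge atoms",
                resname, chain_id, idx,
            )
            continue
        out.append(
            NucleotideSites(
                base_type=base,
                chain_id=chain_id,
                residue_index=idx,
                major_position=np.mean(maj, axis=0),
                minor_position=np.mean(mino, axis=0),
                p_position=coords.get("P"),
                c2p_position=coords.get("C2'") if "C2'" in coords else coords.get("C2*"),
                c4_position=coords.get("C4"),
            )
        )
    return out


def write_pdb(chains: Mapping[str, Sequence[AtomRecord]]) -> str:
    """Serialize grouped atom records back to PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = "ccpdock"
    model = gemmi.Model("1")
    for chain_id, records in chains.items():
        chain = gemmi.Chain(chain_id)
        current: Optional[gemmi.Residue] = None
        current_key = None
        for rec in records:
            key = (rec.residue_index, rec.insertion_code, rec.residue_name)
            if key != current_key:
                if current is not None:
                    chain.add_residue(current)
                current = gemmi.Residue()
                current.name = rec.residue_name
                current.seqid = gemmi.SeqId(rec.residue_index, rec.insertion_code or " ")
                current_key = key
            atom = gemmi.Atom()
            atom.name = rec.atom_name
            atom.pos = gemmi.Position(*rec.position)
            atom.element = gemmi.Element(rec.element or "X")
            atom.occ = 1.0
            atom.b_iso = 0.0
            current.add_atom(atom)
        if current is not None:
            chain.add_residue(current)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def sites_to_tsv(
    protein: Sequence[ProteinSite] = (),
    nucleic: Sequence[NucleotideSites] = (),
) -> str:
    """Export pseudo-atom sets as TSV (chain, index, type, moiety, x, y, z)."""
    rows = []
    for s in protein:
        rows.append((s.chain_id, s.residue_index, s.residue_type, "CB", *s.position))
    for n in nucleic:
        if n.p_position is not None:
            rows.append((n.chain_id, n.residue_index, n.base_type, "P", *n.p_position))
        rows.append((n.chain_id, n.residue_index, n.base_type, "M", *n.major_position))
        rows.append((n.chain_id, n.residue_index, n.base_type, "m", *n.minor_position))
    df = pd.DataFrame(rows, columns=["chain", "index", "type", "moiety", "x", "y", "z"])
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
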