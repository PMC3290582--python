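"""Pose-quality metrics: DNA RMSD after protein superposition, contact sets,
fraction of native contacts, the precision/recall "protein MCC", CCD-based
reports, and rank-enrichment summaries over decoy sets.

Conventions: contacts are measured between pseudo-atoms (C-beta sites vs
P/M/m centers) at a 7 A cutoff; DNA RMSD is measured over the P, C2' and C4
atoms, which exist in every nucleotide regardless of type, after a Kabsch
superposition of the proteins on their C-alpha/C-beta atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import ccp as _ccp

__all__ = [
    "ContactSet",
    "QualityReport",
    "RigidTransform",
    "superpose_protein",
    "dna_rmsd",
    "contact_set",
    "fraction_native_contacts",
    "protein_mcc",
    "rank_enrichment",
    "quality_report",
]

CONTACT_CUTOFF = 7.0  # A


@dataclass(eq=False)
class RigidTransform:
    """x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(eq=False)
class ContactSet:
    """Interface contacts below the cutoff, keyed by residue and by
    (nucleotide, moiety)."""

    cutoff: float
    pairs: frozenset

    def protein_residues(self) -> frozenset:
        return frozenset(p for p, _ in self.pairs)


@dataclass(eq=False)
class QualityReport:
    dna_rmsd: float
    f_nat: float
    protein_mcc: float
    ccd: float


def _superposition_coords(sites: Sequence) -> np.ndarray:
    """C-alpha + C-beta coordinates per residue; residues lacking a distinct
    C-beta contribute their single site position."""
    coords = []
    for s in sites:
        if s.ca_position is not None and not np.allclose(s.ca_position, s.position):
            coords.append(s.ca_position)
        coords.append(s.position)
    return np.array(coords)


def superpose_protein(native_sites: Sequence, model_sites: Sequence) -> RigidTransform:
    """Least-squares (Kabsch) transform mapping the model protein onto the
    native one, built from matched C-alpha/C-beta coordinates."""
    if len(native_sites) != len(model_sites):
        raise ValueError("native and model site lists must have equal length")
    a = _superposition_coords(native_sites)
    b = _superposition_coords(model_sites)
    if a.shape != b.shape:
        raise ValueError("native and model superposition atoms do not match")
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 matched atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - ca, b - cb)
    R = rot.as_matrix()
    return RigidTransform(rotation=R, translation=ca - R @ cb)


def _dna_atoms(na_sites: Sequence) -> dict[tuple[str, int, str], np.ndarray]:
    atoms: dict[tuple[str, int, str], np.ndarray] = {}
    for n in na_sites:
        for label, pos in (("P", n.p_position), ("C2'", n.c2p_position), ("C4", n.c4_position)):
            if pos is not None:
                atoms[(n.chain_id, n.residue_index, label)] = pos
    return atoms


def dna_rmsd(native, model) -> float:
    """RMSD over DNA P/C2'/C4 atoms after protein superposition.

    Atoms are matched by chain and residue index only, so the measure is
    sequence-independent.  5'-terminal nucleotides contribute only C2'/C4.
    """
    tf = superpose_protein(native.protein_sites, model.protein_sites)
    nat = _dna_atoms(native.na_sites)
    mdl = _dna_atoms(model.na_sites)
    keys = sorted(set(nat) & set(mdl))
    if not keys:
        raise ValueError("no matched DNA atoms between native and model")
    a = np.array([nat[k] for k in keys])
    b = tf.apply(np.array([mdl[k] for k in keys]))
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def contact_set(pose, cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """All (protein residue, nucleotide-moiety) pairs separated by < cutoff."""
    pairs = set()
    pos = np.array([s.position for s in pose.protein_sites])
    res_keys = [(s.chain_id, s.residue_index) for s in pose.protein_sites]
    for n in pose.na_sites:
        for moiety, center in (("P", n.p_position), ("M", n.major_position), ("m", n.minor_position)):
            if center is None:
                continue
            d = np.linalg.norm(pos - center, axis=1)
            for i in np.nonzero(d < cutoff)[0]:
                pairs.add((res_keys[i], (n.chain_id, n.residue_index, moiety)))
    return ContactSet(cutoff=cutoff, pairs=frozenset(pairs))


def fraction_native_contacts(native: ContactSet, model: ContactSet) -> float:
    """f_nat = TP / (TP + FN) = |native & model| / |native|."""
    if not native.pairs:
        raise ValueError("native contact set is empty")
    return len(native.pairs & model.pairs) / len(native.pairs)


def protein_mcc(
    native_residues: frozenset | set,
    model_residues: frozenset | set,
    standard_matthews: bool = False,
) -> float:
    """Geometric mean of precision and recall over DNA-contacting residues,
    sqrt(TP/(TP+FP) * TP/(TP+FN)).

    This is the formula used for docking assessment here; it is *not* the
    standard Matthews correlation coefficient (no true negatives enter).
    ``standard_matthews=True`` computes the textbook coefficient instead,
    which additionally needs the universe of residues (the union is used).
    """
    if not native_residues:
        raise ValueError("native residue set is empty")
    tp = len(set(native_residues) & set(model_residues))
    if tp == 0:
        return 0.0
    fp = len(set(model_residues) - set(native_residues))
    fn = len(set(native_residues) - set(model_residues))
    if standard_matthews:
        # degenerate universe: union only, tn = 0
        tn = 0
        denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        return float((tp * tn - fp * fn) / denom) if denom else 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(np.sqrt(precision * recall))


def rank_enrichment(
    decoys,
    selector_key: str,
    truth_key: str,
    subset_size: int,
    top_n: int = 20,
    selector_ascending: bool = True,
    truth_ascending: bool = True,
) -> float:
    """Fraction of the best ``top_n`` decoys by the truth annotation that fall
    within the best ``subset_size`` decoys by the selector annotation.

    E.g. with selector = surface-complementarity rank and truth = RMSD, this
    measures whether geometric pre-ranking retains the low-RMSD poses.
    """
    items = decoys.decoys if hasattr(decoys, "decoys") else list(decoys)
    n = len(items)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds decoy count {n}")
    if top_n > n:
        raise ValueError(f"top_n {top_n} exceeds decoy count {n}")

    def values(key):
        out = []
        for d in items:
            if hasattr(d, "annotations") and key in d.annotations:
                out.append(d.annotations[key])
            else:
                out.append(getattr(d, key))
        return np.asarray(out, dtype=float)

    sel = values(selector_key)
    tru = values(truth_key)
    sel_order = np.argsort(sel if selector_ascending else -sel, kind="stable")
    tru_order = np.argsort(tru if truth_ascending else -tru, kind="stable")
    subset = set(sel_order[:subset_size].tolist())
    top = tru_order[:top_n]
    return float(np.mean([i in subset for i in top]))


def quality_report(native, model, cutoff: float = CONTACT_CUTOFF,
                   native_profile: Optional[_ccp.CCPVector] = None) -> QualityReport:
    """Full per-pose report: DNA RMSD, f_nat, protein MCC and CCD."""
    nat_contacts = contact_set(native, cutoff)
    mdl_contacts = contact_set(model, cutoff)
    nat_prof = native_profile if native_profile is not None else _ccp.ccp_vector(
        native.protein_sites, native.na_sites)
    mdl_prof = _ccp.ccp_vector(model.protein_sites, model.na_sites)
    return QualityReport(
        dna_rmsd=dna_rmsd(native, model),
        f_nat=fraction_native_contacts(nat_contacts, mdl_contacts),
        protein_mcc=protein_mcc(
            nat_contacts.protein_residues(), mdl_contacts.protein_residues()
        ),
        ccd=_ccp.ccd(nat_prof, mdl_prof),
    )
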