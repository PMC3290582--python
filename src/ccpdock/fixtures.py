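"""Synthetic structures and decoy ensembles: everything the rest of the
package needs is generated here, deterministically, from a seed.

``build_bdna`` produces an idealized fiber-model B-DNA duplex (rise 3.38 A,
twist 36 degrees, fixed radial placements for the P, C2', C4 atoms and the
groove centers).  It is a geometric stand-in for a real helix generator: it
honors helical symmetry, strand complementarity/antiparallelism and the
absent 5' phosphate, but carries no sequence-dependent shape.  Groove-edge
base atoms are emitted in small zero-sum clusters around the intended
groove centers so that a write -> parse -> reduce round trip recovers the
same centers.

``make_training_suite`` synthesizes per-complex decoy feature tables whose
CCD ranks are constructed to correlate with a planted weight vector's
score, giving the training stack a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import assess as _assess
from . import ccp as _ccp
from .constants import DEFAULT_EXTENTS, REDUCED_KEY_INDEX, REDUCED_KEYS, RESIDUE_CHARGES
from .dockgen import Decoy, DecoySet
from .structures import AtomRecord, ComplexPose, NucleotideSites, ProteinSite, write_pdb
from .train import TrainingInstance, ccd_rank

__all__ = [
    "SyntheticComplexSpec",
    "BDNADuplex",
    "build_bdna",
    "flip_bases",
    "build_toy_protein",
    "make_decoys",
    "make_training_suite",
]

RISE = 3.38     # A per base-pair step
TWIST = 36.0    # degrees per base-pair step

_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}
_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}
_FLIP = {"A": "G", "G": "A", "C": "T", "T": "C", "U": "C"}

# cylindrical placements (radius A, phase deg relative to the base-pair
# angle) for the emitted atoms; the backbone sits at +/-77 deg so the two
# strands are separated by 154 deg across the minor groove
_BACKBONE_PHASE = 77.0
_R_P, _R_C2P, _R_C4 = 8.9, 7.0, 3.0
_R_GROOVE = 2.0
_GROOVE_PHASE = 8.0  # small per-strand offset so strand centers differ

# groove-edge atoms emitted per base, matching the reduction tables
_MAJOR_ATOMS = {"A": ("N6", "N7", "C5"), "G": ("O6", "N7", "C5"),
                "C": ("N4", "C5", "C6"), "T": ("O4", "C5", "C6"),
                "U": ("O4", "C5", "C6")}
_MINOR_ATOMS = {"A": ("C2", "N3"), "G": ("N2", "N3", "C2"),
                "C": ("O2", "C2"), "T": ("O2", "C2"), "U": ("O2", "C2")}


@dataclass(eq=False)
class SyntheticComplexSpec:
    """Parameters of a synthetic complex / decoy ensemble."""

    dna_sequence: str = "GATTACA"
    protein_layout: Sequence = ()
    rng_seed: int = 0
    decoy_count: int = 100
    translation_scale: float = 5.0   # A, per-axis normal spread
    rotation_scale_deg: float = 20.0

    def __post_init__(self) -> None:
        if len(self.dna_sequence) < 2:
            raise ValueError("DNA sequence must have at least 2 bases")
        if self.decoy_count < 1:
            raise ValueError("decoy_count must be >= 1")


@dataclass(eq=False)
class BDNADuplex:
    """Idealized duplex: atoms grouped by chain plus reduced nucleotide sites."""

    sequence: str
    atoms: dict
    sites: list
    rise: float = RISE
    twist: float = TWIST

    def to_pdb(self) -> str:
        return write_pdb(self.atoms)


def _cyl(radius: float, angle_deg: float, z: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def _resname(base: str, rna: bool) -> str:
    return base if rna else {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}[base]


def flip_bases(sequence: str) -> str:
    """Purine<->purine, pyrimidine<->pyrimidine base flip: A<->G and C<->U
    (C<->T in the DNA alphabet).  An involution that preserves the
    purine/pyrimidine pattern at every position."""
    seq = sequence.upper()
    bad = set(seq) - set(_FLIP)
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    return "".join(_FLIP[b] for b in seq)


def build_bdna(sequence: str, rise: float = RISE, twist: float = TWIST) -> BDNADuplex:
    """Build an idealized antiparallel B-form duplex along the z axis.

    Base pair i sits at height i*rise and angle i*twist.  Strand ``A`` runs
    5'->3' with the given sequence; strand ``B`` carries the reverse
    complement.  Each nucleotide gets a P atom (omitted at its strand's 5'
    terminus), C2' and C4 atoms, and groove-edge atom clusters whose
    centroids are the major/minor groove centers.
    """
    seq = sequence.upper()
    bad = set(seq) - set(_DNA_COMPLEMENT)
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    rna = "U" in seq
    comp = _RNA_COMPLEMENT if rna else _DNA_COMPLEMENT
    n = len(seq)
    atoms: dict[str, list[AtomRecord]] = {"A": [], "B": []}
    sites: list[NucleotideSites] = []

    def emit(chain: str, local_idx: int, base: str, pair_idx: int, sign: float) -> None:
        """One nucleotide of a strand; sign +1 for strand A, -1 for strand B."""
        theta = pair_idx * twist
        z = pair_idx * rise
        resname = _resname(base, rna)
        resnum = local_idx + 1
        recs: list[AtomRecord] = []

        def add(name: str, pos: np.ndarray, element: str) -> None:
            recs.append(AtomRecord(atom_name=name, element=element,
                                   residue_name=resname, residue_index=resnum,
                                   chain_id=chain, position=pos))

        is_5prime = local_idx == 0
        if not is_5prime:
            add("P", _cyl(_R_P, theta + sign * _BACKBONE_PHASE, z), "P")
        add("C2'", _cyl(_R_C2P, theta + sign * (_BACKBONE_PHASE - 15.0), z), "C")
        add("C4", _cyl(_R_C4, theta + sign * 30.0, z), "C")

        minor_center = _cyl(_R_GROOVE, theta + sign * _GROOVE_PHASE, z)
        major_center = _cyl(_R_GROOVE, theta + 180.0 + sign * _GROOVE_PHASE, z)
        for names, center in ((_MAJOR_ATOMS[base], major_center),
                              (_MINOR_ATOMS[base], minor_center)):
            k = len(names)
            for j, name in enumerate(names):
                # zero-sum planar offsets: centroid lands exactly on center
                ang = 2.0 * np.pi * j / k
                off = (0.3 * np.array([np.cos(ang), np.sin(ang), 0.0])
                       if k > 1 else np.zeros(3))
                if k == 2:
                    off = 0.3 * np.array([1.0, 0.0, 0.0]) * (1 if j == 0 else -1)
                add(name, center + off, name[0])
        atoms[chain].extend(recs)
        sites.append(NucleotideSites(
            base_type=base, chain_id=chain, residue_index=resnum,
            major_position=major_center, minor_position=minor_center,
            p_position=None if is_5prime else recs[0].position,
            c2p_position=next(r.position for r in recs if r.atom_name == "C2'"),
            c4_position=next(r.position for r in recs if r.atom_name == "C4"),
        ))

    for i, base in enumerate(seq):
        emit("A", i, base, pair_idx=i, sign=+1.0)
    for j in range(n):
        pair_idx = n - 1 - j  # antiparallel: B's 5' end pairs with A's 3' end
        emit("B", j, comp[seq[pair_idx]], pair_idx=pair_idx, sign=-1.0)
    return BDNADuplex(sequence=seq, atoms=atoms, sites=sites, rise=rise, twist=twist)


def build_toy_protein(
    layout: Sequence,
    rng_seed: int = 0,
    jitter: float = 0.0,
    extent_table: Optional[dict] = None,
    chain_id: str = "P",
) -> list[ProteinSite]:
    """Deterministic pseudo-atom cloud.

    ``layout`` is a sequence of (residue_type, position) pairs; positions are
    3-vectors.  Optional ``jitter`` adds seeded Gaussian noise.  Extents and
    charges come from the default tables unless overridden.
    """
    if not len(layout):
        raise ValueError("layout must be nonempty")
    rng = np.random.default_rng(rng_seed)
    extents = dict(DEFAULT_EXTENTS)
    if extent_table:
        extents.update(extent_table)
    sites = []
    for i, (restype, pos) in enumerate(layout):
        if restype not in extents:
            raise ValueError(f"unknown residue type {restype!r}")
        p = np.asarray(pos, dtype=float) + jitter * rng.standard_normal(3)
        sites.append(ProteinSite(
            residue_type=restype, chain_id=chain_id, residue_index=i + 1,
            position=p, extent=extents[restype],
            charge=RESIDUE_CHARGES[restype],
        ))
    return sites


def _perturbed_na_sites(na_sites: Sequence, R: np.ndarray, t: np.ndarray,
                        center: np.ndarray) -> list:
    out = []
    for n in na_sites:
        def tf(p):
            return None if p is None else (p - center) @ R.T + center + t
        out.append(NucleotideSites(
            base_type=n.base_type, chain_id=n.chain_id,
            residue_index=n.residue_index,
            major_position=tf(n.major_position), minor_position=tf(n.minor_position),
            p_position=tf(n.p_position), c2p_position=tf(n.c2p_position),
            c4_position=tf(n.c4_position),
        ))
    return out


def make_decoys(native: ComplexPose, spec: SyntheticComplexSpec) -> DecoySet:
    """Rigid DNA perturbations of a native pose, seeded and annotated.

    Decoy 1 is always the identity transform.  Each decoy carries its
    realized pose plus ``dna_rmsd`` and ``ccd`` versus the native in its
    annotations.
    """
    rng = np.random.default_rng(spec.rng_seed)
    centers = np.array([n.major_position for n in native.na_sites])
    centroid = centers.mean(axis=0)
    native_profile = _ccp.ccp_vector(native.protein_sites, native.na_sites)
    decoys = []
    for i in range(spec.decoy_count):
        if i == 0:
            R, t = np.eye(3), np.zeros(3)
        else:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = np.radians(spec.rotation_scale_deg) * rng.standard_normal()
            R = Rotation.from_rotvec(angle * axis).as_matrix()
            t = spec.translation_scale * rng.standard_normal(3)
        pose = ComplexPose(
            protein_sites=native.protein_sites,
            na_sites=_perturbed_na_sites(native.na_sites, R, t, centroid),
            pose_id=f"decoy{i + 1:05d}",
        )
        profile = _ccp.ccp_vector(pose.protein_sites, pose.na_sites)
        decoys.append(Decoy(
            pose_id=pose.pose_id, rotation_index=0,
            translation=t, scs=np.nan, scs_rank=i + 1,
            annotations={
                "pose": pose,
                "dna_rmsd": _assess.dna_rmsd(native, pose),
                "ccd": _ccp.ccd(native_profile, profile),
            },
        ))
    return DecoySet(decoys=decoys, top_per_rotation=0, top_total=spec.decoy_count)


def make_training_suite(
    n_complexes: int = 34,
    decoys_per_complex: int = 1000,
    planted_weights: Optional[dict] = None,
    rng_seed: int = 0,
    noise_scale: float = 0.3,
    coulomb_scale: float = 0.3,
) -> list[TrainingInstance]:
    """Synthetic training instances with a recoverable ground truth.

    Decoy features are half-normal draws over the 60-key reduced space; each
    decoy's CCD is the (standardized) planted score plus Gaussian noise of
    relative scale ``noise_scale``, so low CCD ranks concentrate on decoys
    the planted weights favor.  Unreferenced features are pure noise.
    """
    if n_complexes < 1:
        raise ValueError("need at least one complex")
    if planted_weights is None:
        planted_weights = {("ASP", "P"): -1.5, ("LYS", "P"): -1.0,
                           ("ALA", "P"): +1.5, ("PRO", "m"): +1.0}
    w = np.zeros(len(REDUCED_KEYS))
    for key, val in planted_weights.items():
        w[REDUCED_KEY_INDEX[key]] = val
    rng = np.random.default_rng(rng_seed)
    instances = []
    for c in range(n_complexes):
        feats = np.abs(rng.standard_normal((decoys_per_complex, len(REDUCED_KEYS))))
        coulomb = coulomb_scale * rng.standard_normal(decoys_per_complex)
        ccp_norm = 1.0 + np.abs(rng.standard_normal(decoys_per_complex))
        planted_score = feats @ w
        sd = planted_score.std()
        z = (planted_score - planted_score.mean()) / (sd if sd > 0 else 1.0)
        ccd_values = z + noise_scale * rng.standard_normal(decoys_per_complex)
        pose_ids = [f"p{i:05d}" for i in range(decoys_per_complex)]
        instances.append(TrainingInstance(
            complex_id=f"synth{c + 1:03d}",
            features=feats, coulomb=coulomb, ccp_norm=ccp_norm,
            ccd_rank=ccd_rank(ccd_values, pose_ids), pose_ids=pose_ids,
        ))
    return instances
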