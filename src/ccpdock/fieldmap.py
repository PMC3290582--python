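"""DNA-binding field mapping: probe a protein's surroundings with a test
moiety (phosphate, major- or minor-groove center) the way a test charge
probes an electrostatic field.

The field value at a point is the score the scoring function would assign a
lone nucleotide center of that type placed there:

    value(x) = sum_sites  w(aa, probe) * f(|x - site|, <e>)
             + [probe == P]  sum_sites  q_site * (-1) * f(|x - site|, <e>)

so the phosphate field additionally carries the protein's electrostatics.
Lower values are more favorable.  Tracks along a posed DNA evaluate the
three fields at each nucleotide's own centers, per strand, starting at base
pair step 2 (the 5'-terminal phosphate does not exist).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ccp import pair_energy
from .constants import MOIETIES
from .scoring import WeightVector, default_weights

__all__ = [
    "FieldSample",
    "GrooveTrack",
    "probe_field",
    "surface_points",
    "track_along_dna",
    "field_to_pdb",
    "field_to_tsv",
]


@dataclass(eq=False)
class FieldSample:
    point: np.ndarray
    probe: str
    value: float


@dataclass(eq=False)
class GrooveTrack:
    """Per-base-step field values along one DNA strand.

    ``start_index`` is 2: the first base-pair step with a phosphate.
    Values are dicts probe -> list, one entry per step."""

    strand_id: str
    start_index: int
    values: dict


def probe_field(
    protein_sites: Sequence,
    points: np.ndarray | Sequence,
    probe: str,
    weights: Optional[WeightVector] = None,
) -> list[FieldSample]:
    """Evaluate the test-moiety field at each point (vectorized)."""
    if probe not in MOIETIES:
        raise ValueError(f"unknown probe {probe!r}; expected one of {MOIETIES}")
    if weights is None:
        weights = default_weights()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pos = np.array([s.position for s in protein_sites])
    ext = np.array([s.extent for s in protein_sites])
    w = np.array([weights.pair_weights.get((s.residue_type, probe), 0.0)
                  for s in protein_sites])
    q = np.array([s.charge for s in protein_sites], dtype=float)
    values = np.zeros(len(pts))
    for i, p in enumerate(pts):
        f = pair_energy(np.linalg.norm(pos - p, axis=1), ext)
        v = float(np.sum(w * f))
        if probe == "P":
            v += float(np.sum(q * (-1.0) * f)) * weights.coulomb_weight
        values[i] = v
    return [FieldSample(point=p, probe=probe, value=v) for p, v in zip(pts, values)]


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def surface_points(
    protein_sites: Sequence,
    shell_offset: float = 3.0,
    density: int = 64,
    tolerance: float = 0.5,
) -> np.ndarray:
    """Quasi-uniform probe points on an offset shell around the site cloud.

    Candidate points are Fibonacci-sphere samples of radius ``shell_offset``
    around every site; a candidate is kept when its distance to the nearest
    site lies within ``shell_offset`` +/- ``tolerance``.  ``density`` is the
    number of candidates per site.
    """
    if not len(protein_sites):
        raise ValueError("need at least one protein site")
    pos = np.array([s.position for s in protein_sites])
    unit = _fibonacci_sphere(density)
    candidates = (pos[:, None, :] + shell_offset * unit[None, :, :]).reshape(-1, 3)
    d = np.min(np.linalg.norm(candidates[:, None, :] - pos[None, :, :], axis=2), axis=1)
    keep = np.abs(d - shell_offset) <= tolerance
    return candidates[keep]


def track_along_dna(
    protein_sites: Sequence,
    na_sites: Sequence,
    weights: Optional[WeightVector] = None,
) -> dict[str, GrooveTrack]:
    """Evaluate the three probe fields at each nucleotide's own centers,
    one track per strand (chain), starting at base-pair step 2."""
    strands: dict[str, list] = {}
    for n in na_sites:
        strands.setdefault(n.chain_id, []).append(n)
    if not strands or all(len(v) < 2 for v in strands.values()):
        raise ValueError("tracking needs a DNA of at least 2 base pairs")
    tracks: dict[str, GrooveTrack] = {}
    for chain_id, nucs in strands.items():
        nucs = sorted(nucs, key=lambda n: n.residue_index)
        vals: dict[str, list] = {m: [] for m in MOIETIES}
        for n in nucs[1:]:  # step index starts at two: skip the 5' terminus
            centers = {"P": n.p_position, "M": n.major_position, "m": n.minor_position}
            for m in MOIETIES:
                c = centers[m]
                if c is None:
                    vals[m].append(np.nan)
                else:
                    vals[m].append(probe_field(protein_sites, [c], m, weights)[0].value)
        tracks[chain_id] = GrooveTrack(strand_id=chain_id, start_index=2, values=vals)
    return tracks


def field_to_tsv(samples: Sequence[FieldSample]) -> str:
    lines = ["x\ty\tz\tprobe\tvalue"]
    for s in samples:
        lines.append(f"{s.point[0]:.3f}\t{s.point[1]:.3f}\t{s.point[2]:.3f}"
                     f"\t{s.probe}\t{s.value:.6f}")
    return "\n".join(lines) + "\n"


def field_to_pdb(samples: Sequence[FieldSample]) -> str:
    """Probe points as HETATM pseudo-atoms with the field value in the
    B-factor column (standard trick for coloring by value)."""
    lines = []
    for i, s in enumerate(samples, start=1):
        b = max(-999.99, min(999.99, s.value))
        lines.append(
            f"HETATM{i:5d}  {s.probe:<3s}PRB X{i % 10000:4d}    "
            f"{s.point[0]:8.3f}{s.point[1]:8.3f}{s.point[2]:8.3f}"
            f"{1.00:6.2f}{b:6.2f}           X"
        )
    return "\n".join(lines + ["END"]) + "\n"
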