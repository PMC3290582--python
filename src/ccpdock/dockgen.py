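"""Rigid-body decoy generation by grid-based FFT surface-complementarity search.

The classic Katchalski-Katzir scheme: the static molecule (the protein) is
rasterized onto a cubic grid with a thin +1 surface shell and a penalized
core; the mobile molecule (the DNA) is rasterized as +1 occupancy.  For each
sampled rotation of the mobile molecule, the translational cross-correlation
of the two grids — the surface complementarity score (SCS) — is evaluated
for every voxel shift at once via FFT, and the best translations per
rotation are retained, pooled and ranked.

Desk-scale defaults (1.5 A grid, 30 degree rotations) are deliberately
coarser than production FFT docking (0.5 A / 10 degrees, which this code
also accepts, only slower).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.fft
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "VoxelGrid",
    "RotationSet",
    "Decoy",
    "DecoySet",
    "rasterize",
    "rotation_set",
    "scs_search",
    "transform_coords",
]

DEFAULT_SPACING = 1.5     # A
DEFAULT_ROT_SPACING = 30  # degrees
DEFAULT_PROBE_RADIUS = 1.8  # A, van der Waals proxy for voxel occupancy
DEFAULT_CORE_PENALTY = -15.0


@dataclass(eq=False)
class VoxelGrid:
    """Labelled cubic grid: 0 empty, +1 surface, core carries the penalty."""

    spacing: float
    origin: np.ndarray
    labels: np.ndarray


@dataclass(eq=False)
class RotationSet:
    """Deduplicated proper rotations from a regular Euler-angle grid."""

    spacing_deg: float
    rotations: list


@dataclass(eq=False)
class Decoy:
    """One retained rigid pose of the mobile molecule."""

    pose_id: str
    rotation_index: int
    translation: np.ndarray  # A; applied after rotation about the mobile centroid
    scs: float
    scs_rank: int = 0
    annotations: dict = field(default_factory=dict)


@dataclass(eq=False)
class DecoySet:
    decoys: list
    top_per_rotation: int = 0
    top_total: int = 0

    def __len__(self) -> int:
        return len(self.decoys)

    def annotation_array(self, key: str) -> np.ndarray:
        return np.array([d.annotations.get(key, getattr(d, key, np.nan))
                         for d in self.decoys], dtype=float)


def _occupancy(coords: np.ndarray, spacing: float, probe_radius: float,
               padding: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean occupancy grid: voxel centers within probe_radius of any atom."""
    coords = np.asarray(coords, dtype=float)
    lo = coords.min(axis=0) - probe_radius - padding
    hi = coords.max(axis=0) + probe_radius + padding
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    axes = [lo[i] + spacing * np.arange(shape[i]) for i in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    d, _ = cKDTree(coords).query(centers, k=1)
    occ = (d <= probe_radius).reshape(tuple(shape))
    return occ, lo


def rasterize(
    coords_or_sites,
    spacing: float = DEFAULT_SPACING,
    role: str = "static",
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    core_penalty: float = DEFAULT_CORE_PENALTY,
    padding: float = 0.0,
) -> VoxelGrid:
    """Convert a coordinate cloud into a labelled voxel grid.

    ``role='static'``: one-voxel surface shell = +1, interior = core_penalty.
    ``role='mobile'``: every occupied voxel = +1.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if role not in ("static", "mobile"):
        raise ValueError("role must be 'static' or 'mobile'")
    coords = _as_coords(coords_or_sites)
    if coords.size == 0:
        raise ValueError("cannot rasterize an empty coordinate set")
    occ, origin = _occupancy(coords, spacing, probe_radius, padding)
    labels = np.zeros(occ.shape)
    if role == "mobile":
        labels[occ] = 1.0
    else:
        core = ndimage.binary_erosion(occ)  # interior: all 6-neighbours occupied
        labels[occ & ~core] = 1.0
        labels[core] = core_penalty
    return VoxelGrid(spacing=spacing, origin=origin, labels=labels)


def _as_coords(obj) -> np.ndarray:
    arr = np.asarray(obj, dtype=object)
    if arr.dtype != object:
        return np.asarray(obj, dtype=float)
    try:
        return np.asarray(obj, dtype=float)
    except (TypeError, ValueError):
        return np.array([s.position for s in obj], dtype=float)


def _angular_distance_deg(q: np.ndarray, qs: np.ndarray) -> np.ndarray:
    dots = np.abs(qs @ q)
    return np.degrees(2.0 * np.arccos(np.clip(dots, -1.0, 1.0)))


def rotation_set(spacing_deg: float = DEFAULT_ROT_SPACING) -> RotationSet:
    """Enumerate a z-y-z Euler grid at the given spacing and deduplicate
    rotations closer than half the spacing in angular distance.

    Deterministic; the identity is always first.  At 90 degrees the result
    is exactly the 24-element rotation group of the cube.
    """
    if not 0 < spacing_deg <= 90:
        raise ValueError("rotational spacing must be in (0, 90] degrees")
    alphas = np.arange(0.0, 360.0, spacing_deg)
    betas = np.arange(0.0, 180.0 + 1e-9, spacing_deg)
    gammas = np.arange(0.0, 360.0, spacing_deg)
    kept_mats: list[np.ndarray] = []
    kept_quats: list[np.ndarray] = []
    for a in alphas:
        for b in betas:
            for g in gammas:
                rot = Rotation.from_euler("zyz", [a, b, g], degrees=True)
                q = rot.as_quat()
                if kept_quats:
                    d = _angular_distance_deg(q, np.array(kept_quats))
                    if np.min(d) < 0.5 * spacing_deg:
                        continue
                kept_quats.append(q)
                kept_mats.append(rot.as_matrix())
    # put the identity first for reproducible indexing
    order = np.argsort([0 if np.allclose(m, np.eye(3)) else 1 for m in kept_mats],
                       kind="stable")
    return RotationSet(spacing_deg=spacing_deg, rotations=[kept_mats[i] for i in order])


def correlate_grids(static: np.ndarray, mobile: np.ndarray,
                    use_fft: bool = True) -> np.ndarray:
    """Translational cross-correlation C[t] = sum_x S[x] * M[x - t] for all
    voxel shifts t, linear (zero-padded) so no wrap-around occurs.

    Shift t along each axis ranges over -(m_n - 1) .. (s_n - 1) and is stored
    FFT-style: index 0 is t = 0, negative shifts wrap at the end.
    """
    shape = tuple(s + m - 1 for s, m in zip(static.shape, mobile.shape))
    if use_fft:
        fs = scipy.fft.rfftn(static, shape)
        fm = scipy.fft.rfftn(mobile, shape)
        corr = scipy.fft.irfftn(fs * np.conj(fm), shape)
        return corr
    corr = np.zeros(shape)
    s_nz = np.argwhere(static != 0)
    m_nz = np.argwhere(mobile != 0)
    for sx in s_nz:
        for mx in m_nz:
            t = tuple((sx - mx) % np.array(shape))
            corr[t] += static[tuple(sx)] * mobile[tuple(mx)]
    return corr


def _wrap_shift(idx: np.ndarray, shape: tuple[int, ...],
                static_shape: tuple[int, ...]) -> np.ndarray:
    # padded shape = s + m - 1; indices >= s encode negative shifts
    shape = np.asarray(shape)
    s = np.asarray(static_shape)
    return np.where(idx < s, idx, idx - shape)


def scs_search(
    static: VoxelGrid,
    mobile_coords,
    rotations: RotationSet,
    top_per_rotation: int = 10,
    top_total: Optional[int] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    pad_static: bool = False,
) -> DecoySet:
    """Exhaustive translational search for every rotation of the mobile
    molecule; keep the best ``top_per_rotation`` translations per rotation,
    pool, sort by SCS descending and keep ``top_total``.

    Each decoy's pose is: rotate the mobile coordinates about their centroid,
    then translate by ``decoy.translation`` (Angstroms).  Ties in SCS break
    stably by (rotation index, lexicographic translation).  A mobile molecule
    larger than the static grid is an error unless ``pad_static`` is set, in
    which case the static grid is zero-padded to accommodate it.
    """
    mobile = _as_coords(mobile_coords)
    centroid = mobile.mean(axis=0)
    if mobile.shape[0] < 1:
        raise ValueError("mobile molecule has no coordinates")
    sp = static.spacing
    records = []
    for ri, R in enumerate(rotations.rotations):
        rotated = (mobile - centroid) @ R.T + centroid
        mgrid = rasterize(rotated, spacing=sp, role="mobile", probe_radius=probe_radius)
        slabels = static.labels
        if any(m > s for m, s in zip(mgrid.labels.shape, slabels.shape)):
            if not pad_static:
                raise ValueError("mobile molecule does not fit inside the static grid")
            pad = [(0, max(0, m - s))
                   for m, s in zip(mgrid.labels.shape, slabels.shape)]
            slabels = np.pad(slabels, pad)
        corr = correlate_grids(slabels, mgrid.labels)
        flat = corr.reshape(-1)
        k = min(top_per_rotation, flat.size)
        best = np.argpartition(-flat, k - 1)[:k]
        shifts = np.array(np.unravel_index(best, corr.shape)).T
        shifts = _wrap_shift(shifts, corr.shape, slabels.shape)
        for score, shift in zip(flat[best], shifts):
            # mobile voxel i maps to static voxel i + shift
            disp = (static.origin - mgrid.origin) + shift * sp
            records.append((float(score), ri, tuple(shift), disp))
    # sort by SCS descending, ties by rotation index then translation
    records.sort(key=lambda r: (-r[0], r[1], r[2]))
    if top_total is not None:
        records = records[:top_total]
    decoys = [
        Decoy(
            pose_id=f"d{rank:06d}",
            rotation_index=ri,
            translation=np.asarray(disp, dtype=float),
            scs=score,
            scs_rank=rank,
        )
        for rank, (score, ri, _shift, disp) in enumerate(records, start=1)
    ]
    return DecoySet(decoys=decoys, top_per_rotation=top_per_rotation,
                    top_total=top_total or len(decoys))


def transform_coords(coords: np.ndarray, rotation: np.ndarray,
                     translation: np.ndarray,
                     centroid: Optional[np.ndarray] = None) -> np.ndarray:
    """Realize a decoy pose: rotate about the centroid, then translate."""
    coords = np.asarray(coords, dtype=float)
    c = coords.mean(axis=0) if centroid is None else np.asarray(centroid)
    return (coords - c) @ np.asarray(rotation).T + c + np.asarray(translation)
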