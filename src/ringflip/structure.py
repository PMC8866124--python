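"""Geometry engine: dihedrals, superposition, morphing, pocket volumes.

Operates on a light-weight :class:`Structure` of heavy-atom Cartesian
coordinates (Angstrom, PDB atom naming).  The void-volume machinery
re-creates a POVME-style calculation: a cubic grid inside an inclusion
sphere, exclusion of points within (van der Waals radius + probe
cutoff) of any atom, and a 6-connected flood fill keeping the
contiguous component around a seed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .constants import HYDROGEN_CUTOFF, VDW_DEFAULT, VDW_RADII
from .errors import StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "MorphTrajectory",
    "PocketDefinition",
    "VolumeProfile",
    "dihedral_angle",
    "chi2_dihedral",
    "superpose",
    "linear_morph",
    "mutate_to_glycine",
    "pocket_volume",
    "volume_profile",
    "ring_centroid",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Structure:
    """Atomic model: parallel per-atom arrays plus coordinates in Angstrom."""

    chains: np.ndarray  # dtype object, chain ids
    res_nums: np.ndarray  # int
    res_names: np.ndarray  # dtype object
    atom_names: np.ndarray  # dtype object
    elements: np.ndarray  # dtype object
    coords: np.ndarray  # (n, 3) float
    vdw_override: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        keys = self.keys()
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, residue, atom-name) keys")

    @classmethod
    def from_atoms(cls, atoms: Sequence[tuple], vdw_override=None) -> "Structure":
        """Build from (chain, res_num, res_name, atom_name, element, xyz) tuples."""
        chains = np.array([a[0] for a in atoms], dtype=object)
        res_nums = np.array([int(a[1]) for a in atoms], dtype=int)
        res_names = np.array([a[2] for a in atoms], dtype=object)
        atom_names = np.array([a[3] for a in atoms], dtype=object)
        elements = np.array([a[4] for a in atoms], dtype=object)
        coords = np.array([a[5] for a in atoms], dtype=float)
        return cls(chains, res_nums, res_names, atom_names, elements, coords,
                   vdw_override=dict(vdw_override or {}))

    def __len__(self) -> int:
        return len(self.coords)

    def keys(self) -> list[tuple]:
        return list(zip(self.chains, self.res_nums, self.atom_names))

    def key_index(self) -> dict:
        return {k: i for i, k in enumerate(self.keys())}

    def subset(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            self.chains[mask], self.res_nums[mask], self.res_names[mask],
            self.atom_names[mask], self.elements[mask], self.coords[mask],
            vdw_override=dict(self.vdw_override),
        )

    def copy(self) -> "Structure":
        return Structure(
            self.chains.copy(), self.res_nums.copy(), self.res_names.copy(),
            self.atom_names.copy(), self.elements.copy(), self.coords.copy(),
            vdw_override=dict(self.vdw_override),
        )

    def residue_mask(self, res_num: int, chain: str | None = None) -> np.ndarray:
        mask = self.res_nums == int(res_num)
        if chain is not None:
            mask &= self.chains == chain
        return mask

    def atom_coord(self, res_num: int, atom_name: str, chain: str | None = None) -> np.ndarray:
        mask = self.residue_mask(res_num, chain) & (self.atom_names == atom_name)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise StructureError(
                f"atom {atom_name!r} of residue {res_num} not found"
            )
        return self.coords[idx[0]]

    def vdw_radii(self) -> np.ndarray:
        radii = np.empty(len(self))
        for i, el in enumerate(self.elements):
            el_up = str(el).upper()
            radii[i] = self.vdw_override.get(
                el_up, VDW_RADII.get(el_up, VDW_DEFAULT)
            )
        return radii


@dataclass
class MorphTrajectory:
    """Ordered interpolation frames between two conformations."""

    frames: list[Structure]
    fractions: np.ndarray  # lambda in [0, 1] per frame

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.frames) != self.fractions.size:
            raise StructureError("frames and fractions differ in length")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class PocketDefinition:
    """Inclusion sphere, grid spacing and probe cutoff for pocket gridding."""

    center: np.ndarray  # Angstrom
    radius: float = 8.0  # Angstrom
    spacing: float = 0.5  # grid spacing delta, Angstrom
    cutoff: float = HYDROGEN_CUTOFF  # probe cutoff, Angstrom
    seed_point: np.ndarray | None = None  # defaults to the center

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not self.radius > 0:
            raise StructureError("inclusion radius must be positive")
        if not self.spacing > 0:
            raise StructureError("grid spacing must be positive")
        if self.cutoff < 0:
            raise StructureError("cutoff must be non-negative")
        if self.seed_point is None:
            self.seed_point = self.center.copy()
        else:
            self.seed_point = np.asarray(self.seed_point, dtype=float)


@dataclass
class VolumeProfile:
    """Pocket volume per morph frame and the expansion statistic."""

    volumes: np.ndarray  # Angstrom^3 per frame
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.volumes < 0):
            raise StructureError("volumes must be non-negative")

    @property
    def expansion(self) -> float:
        """max volume - frame-0 volume, Angstrom^3."""
        return float(np.max(self.volumes) - self.volumes[0])


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees), IUPAC convention, atan2 construction."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def fold_chi2(angle_deg: float) -> float:
    """Fold an aromatic chi2 into (-90, +90] using ring two-fold symmetry."""
    a = (float(angle_deg) + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def chi2_dihedral(s: Structure, res_num: int, chain: str | None = None) -> float:
    """Aromatic chi2 (CA-CB-CG-CD1) in degrees, folded into (-90, +90]."""
    pts = []
    for name in ("CA", "CB", "CG", "CD1"):
        try:
            pts.append(s.atom_coord(res_num, name, chain))
        except StructureError:
            raise StructureError(
                f"residue {res_num}: atom {name} required for chi2 is missing"
            ) from None
    return fold_chi2(dihedral_angle(*pts))


def superpose(
    mobile: Structure,
    target: Structure,
    selection: Sequence[tuple] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, Structure]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    ``selection`` is a list of (chain, res_num, atom_name) keys; by
    default the intersection of atom keys is used.  Returns (rotation,
    translation, rmsd, transformed mobile): ``x_new = x @ R.T + t``.
    """
    mob_idx = mobile.key_index()
    tgt_idx = target.key_index()
    if selection is None:
        selection = [k for k in mobile.keys() if k in tgt_idx]
    try:
        mi = [mob_idx[k] for k in selection]
        ti = [tgt_idx[k] for k in selection]
    except KeyError as exc:
        raise StructureError(f"selection key {exc} missing") from None
    if len(selection) < 3:
        raise StructureError("need >= 3 matched atoms for superposition")
    x = mobile.coords[mi]
    y = target.coords[ti]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise StructureError("degenerate (collinear) selection")
    h = xc.T @ yc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = y.mean(axis=0) - x.mean(axis=0) @ rot.T
    moved = mobile.copy()
    moved.coords = mobile.coords @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved.coords[mi] - y) ** 2, axis=1))))
    return rot, trans, rmsd, moved


def linear_morph(
    a: Structure,
    b: Structure,
    n_frames: int = 11,
    do_superpose: bool = True,
) -> MorphTrajectory:
    """Superposition followed by per-atom linear Cartesian interpolation.

    Frame i has coordinates ``(1 - l_i) a + l_i b`` with
    ``l_i = i / (n_frames - 1)`` over the shared atom keys; atoms
    missing from either end are dropped (and logged).
    """
    if n_frames < 2:
        raise StructureError("need at least 2 frames")
    keys_a = a.key_index()
    keys_b = b.key_index()
    shared = [k for k in a.keys() if k in keys_b]
    if not shared:
        raise StructureError("no shared atoms between the two structures")
    dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if dropped:
        logger.info("linear_morph: dropped %d unshared atoms", dropped)
    a_sub = a.subset([keys_a[k] for k in shared])
    b_sub = b.subset([keys_b[k] for k in shared])
    if do_superpose:
        _, _, rmsd, b_sub = superpose(b_sub, a_sub)
        logger.info("linear_morph: superposition RMSD %.3f A", rmsd)
    fracs = np.linspace(0.0, 1.0, n_frames)
    frames = []
    for lam in fracs:
        f = a_sub.copy()
        f.coords = (1.0 - lam) * a_sub.coords + lam * b_sub.coords
        frames.append(f)
    return MorphTrajectory(frames, fracs)


def mutate_to_glycine(s: Structure, res_num: int, chain: str | None = None) -> Structure:
    """Remove the side chain (CB and beyond) and rename the residue GLY.

    Backbone N, CA, C, O (and OXT) keep their coordinates bit-identically.
    """
    res_mask = s.residue_mask(res_num, chain)
    if not np.any(res_mask):
        raise StructureError(f"residue {res_num} not present")
    drop = res_mask & ~np.isin(s.atom_names.astype(str), list(BACKBONE_ATOMS))
    out = s.subset(~drop)
    out.res_names = out.res_names.copy()
    out.res_names[out.residue_mask(res_num, chain)] = "GLY"
    return out


def pocket_volume(
    s: Structure,
    pocket: PocketDefinition,
    allow_closed: bool = False,
) -> float:
    """Grid-based pocket volume in Angstrom^3.

    Cubic grid of spacing delta with the origin snapped to the
    inclusion-sphere center; grid points within (vdW radius + cutoff) of
    any atom center are deleted; the 6-connected contiguous component
    containing the seed point is kept; volume = count * delta^3.

    If the seed point itself is excluded the pocket is closed at this
    frame: a :class:`StructureError` is raised unless ``allow_closed``
    is set, in which case 0.0 is returned (documented fallback).
    """
    delta = pocket.spacing
    n = int(np.ceil(pocket.radius / delta))
    axis = delta * np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + pocket.center
    inside = (
        np.sum((pts - pocket.center) ** 2, axis=1) <= pocket.radius**2
    ).reshape(gx.shape)

    free = inside.copy().reshape(-1)
    if len(s):
        tree = cKDTree(pts)
        radii = s.vdw_radii() + pocket.cutoff
        for r in np.unique(radii):
            atoms = s.coords[radii == r]
            hits = tree.query_ball_point(atoms, r)
            for h in hits:
                free[h] = False
    free = free.reshape(gx.shape)

    seed_rel = (pocket.seed_point - pocket.center) / delta
    seed_idx = tuple(int(round(c)) + n for c in seed_rel)
    if any(i < 0 or i >= 2 * n + 1 for i in seed_idx) or not free[seed_idx]:
        if allow_closed:
            return 0.0
        raise StructureError(
            "seed point lies in excluded space; pocket closed"
        )
    labels, _ = ndimage.label(free, structure=ndimage.generate_binary_structure(3, 1))
    count = int(np.sum(labels == labels[seed_idx]))
    return count * delta**3


def volume_profile(
    traj: MorphTrajectory,
    pocket: PocketDefinition,
    glycine_target: int | None = None,
    chain: str | None = None,
) -> VolumeProfile:
    """Pocket volume per trajectory frame.

    When ``glycine_target`` is given, that residue is replaced by
    glycine in every frame before gridding (so the full pocket volume is
    measured, not the space already taken by the target side chain).
    Frames whose pocket is closed report volume 0.
    """
    vols = []
    for frame in traj.frames:
        s = frame
        if glycine_target is not None:
            s = mutate_to_glycine(s, glycine_target, chain)
        vols.append(pocket_volume(s, pocket, allow_closed=True))
    return VolumeProfile(np.asarray(vols), traj.fractions)


def ring_centroid(s: Structure, res_num: int, chain: str | None = None) -> np.ndarray:
    """Centroid of the aromatic ring atoms (CG, CD1, CD2, CE1, CE2, CZ)."""
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    pts = []
    for nm in names:
        try:
            pts.append(s.atom_coord(res_num, nm, chain))
        except StructureError:
            continue
    if not pts:
        raise StructureError(f"residue {res_num} has no ring atoms")
    return np.mean(pts, axis=0)
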