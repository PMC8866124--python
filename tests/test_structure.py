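"""Tests of dihedrals, superposition, morphing and pocket-volume gridding."""

import numpy as np
import pytest

from ringflip.errors import StructureError
from ringflip.structure import (
    MorphTrajectory,
    PocketDefinition,
    Structure,
    chi2_dihedral,
    dihedral_angle,
    fold_chi2,
    linear_morph,
    mutate_to_glycine,
    pocket_volume,
    ring_centroid,
    superpose,
    volume_profile,
)
from ringflip.synthetic import make_breathing_cage


def brute_force_dihedral(p0, p1, p2, p3):
    """Independent cross-product construction of the signed dihedral.

    Magnitude from the plane normals' arccos, sign from the triple
    product of the normals with the central bond (IUPAC convention).
    """
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    sign = np.sign(np.dot(np.cross(n1, n2), b2))
    return sign * ang if sign != 0 else ang


def tyrosine_like(chi2_deg: float) -> Structure:
    """Minimal residue with CA-CB-CG-CD1 set to a prescribed chi2."""
    chi = np.radians(chi2_deg)
    atoms = [
        ("A", 526, "TYR", "CA", "C", [0.0, 1.5, 0.0]),
        ("A", 526, "TYR", "CB", "C", [0.0, 0.0, 0.0]),
        ("A", 526, "TYR", "CG", "C", [1.4, -0.5, 0.0]),
        # place CD1 by rotating about the CB->CG axis
        ("A", 526, "TYR", "CD1", "C", None),
    ]
    cb = np.array(atoms[1][5])
    cg = np.array(atoms[2][5])
    axis = (cg - cb) / np.linalg.norm(cg - cb)
    # reference direction perpendicular to the axis, in the CA plane
    ca = np.array(atoms[0][5])
    ref = ca - cb - np.dot(ca - cb, axis) * axis
    ref /= np.linalg.norm(ref)
    perp = np.cross(axis, ref)
    cd1 = cg + 1.4 * (-np.cos(chi) * ref - np.sin(chi) * perp)
    atoms[3] = ("A", 526, "TYR", "CD1", "C", list(cd1))
    return Structure.from_atoms(atoms)


class TestDihedral:
    def test_coplanar_cis_geometry_is_zero(self):
        p = [np.array(x, float) for x in
             [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]]
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_on_random_coordinates(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            a = dihedral_angle(*pts)
            b = brute_force_dihedral(*pts)
            assert a == pytest.approx(b, abs=1e-6)

    @pytest.mark.parametrize("chi", [0.0, 2.0, 45.0, -41.0, -75.0, 120.0])
    def test_chi2_constructed_geometry(self, chi):
        s = tyrosine_like(chi)
        expected = fold_chi2(chi)
        assert chi2_dihedral(s, 526) == pytest.approx(expected, abs=1e-6)

    def test_fold_respects_ring_symmetry(self):
        assert fold_chi2(95.0) == pytest.approx(-85.0)
        assert fold_chi2(-95.0) == pytest.approx(85.0)
        assert fold_chi2(180.0) == pytest.approx(0.0)

    def test_missing_atom_named_in_error(self):
        s = tyrosine_like(10.0)
        s = s.subset(s.atom_names != "CD1")
        with pytest.raises(StructureError, match="CD1"):
            chi2_dihedral(s, 526)


def random_structure(n=20, seed=0) -> Structure:
    rng = np.random.default_rng(seed)
    atoms = [("A", i + 1, "ALA", "CA", "C", rng.normal(size=3) * 5)
             for i in range(n)]
    return Structure.from_atoms(atoms)


class TestSuperpose:
    def test_identity_on_identical_structures(self):
        s = random_structure()
        rot, trans, rmsd, moved = superpose(s, s)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self):
        from scipy.spatial.transform import Rotation

        s = random_structure(seed=3)
        rot_true = Rotation.from_euler("zyx", [30, -20, 50], degrees=True)
        moved = s.copy()
        moved.coords = s.coords @ rot_true.as_matrix().T + [1.0, -2.0, 3.0]
        rot, trans, rmsd, back = superpose(moved, s)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, rot_true.inv().as_matrix(), atol=1e-6)

    def test_translation_only(self):
        s = random_structure(seed=4)
        moved = s.copy()
        moved.coords = s.coords + [5.0, 0.0, -2.0]
        rot, trans, rmsd, _ = superpose(moved, s)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, [-5.0, 0.0, 2.0], atol=1e-9)

    def test_degenerate_selection_rejected(self):
        atoms = [("A", i, "ALA", "CA", "C", [float(i), 0, 0]) for i in range(4)]
        line = Structure.from_atoms(atoms)
        with pytest.raises(StructureError):
            superpose(line, line)


class TestMorph:
    def test_endpoints_and_midframe(self):
        a = random_structure(seed=5)
        b = a.copy()
        b.coords = a.coords + [2.0, 0.0, 0.0]
        traj = linear_morph(a, b, n_frames=5, do_superpose=False)
        np.testing.assert_allclose(traj.frames[0].coords, a.coords)
        np.testing.assert_allclose(traj.frames[-1].coords, b.coords)
        np.testing.assert_allclose(
            traj.frames[2].coords, 0.5 * (a.coords + b.coords)
        )

    def test_displacement_linear_in_frame_index(self):
        rng = np.random.default_rng(9)
        a = random_structure(seed=6)
        b = a.copy()
        b.coords = a.coords + rng.normal(size=a.coords.shape)
        traj = linear_morph(a, b, n_frames=9, do_superpose=False)
        d1 = traj.frames[1].coords - traj.frames[0].coords
        for i in range(2, 9):
            di = traj.frames[i].coords - traj.frames[0].coords
            assert np.max(np.abs(di - i * d1)) < 1e-9

    def test_empty_intersection_rejected(self):
        a = random_structure(seed=7)
        b = a.copy()
        b.atom_names = np.array(["CB"] * len(b), dtype=object)
        with pytest.raises(StructureError):
            linear_morph(a, b)


def tyrosine_full() -> Structure:
    rng = np.random.default_rng(2)
    backbone = [("A", 526, "TYR", n, n[0], rng.normal(size=3))
                for n in ("N", "CA", "C", "O")]
    side = [("A", 526, "TYR", n, "C" if not n.startswith("O") else "O",
             rng.normal(size=3))
            for n in ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")]
    return Structure.from_atoms(backbone + side)


class TestMutateToGlycine:
    def test_tyrosine_loses_eight_heavy_sidechain_atoms(self):
        s = tyrosine_full()
        out = mutate_to_glycine(s, 526)
        assert len(s) - len(out) == 8
        assert set(out.res_names) == {"GLY"}

    def test_backbone_bit_identical(self):
        s = tyrosine_full()
        out = mutate_to_glycine(s, 526)
        for name in ("N", "CA", "C", "O"):
            np.testing.assert_array_equal(
                s.atom_coord(526, name), out.atom_coord(526, name)
            )

    def test_glycine_unchanged(self):
        atoms = [("A", 5, "GLY", n, n[0], [float(i), 0, 0])
                 for i, n in enumerate(("N", "CA", "C", "O"))]
        s = Structure.from_atoms(atoms)
        out = mutate_to_glycine(s, 5)
        np.testing.assert_array_equal(out.coords, s.coords)

    def test_absent_residue_rejected(self):
        with pytest.raises(StructureError):
            mutate_to_glycine(tyrosine_full(), 999)


class TestPocketVolume:
    def test_empty_structure_gives_sphere_volume(self):
        empty = Structure.from_atoms([("A", 1, "DUM", "C1", "C", [99.0, 99, 99])])
        p = PocketDefinition(center=[0.0, 0, 0], radius=5.0, spacing=0.5)
        v = pocket_volume(empty, p)
        analytic = 4 / 3 * np.pi * 5.0**3
        area = 4 * np.pi * 5.0**2
        assert abs(v - analytic) < 2 * 0.5 * area

    def test_single_central_atom_gives_shell_volume(self):
        s = Structure.from_atoms([("A", 1, "DUM", "C1", "C", [0.0, 0, 0])])
        p = PocketDefinition(center=[0.0, 0, 0], radius=6.0, spacing=0.5,
                             seed_point=[0.0, 0.0, 4.0])
        v = pocket_volume(s, p)
        excl = 1.70 + 1.09
        analytic = 4 / 3 * np.pi * (6.0**3 - excl**3)
        assert v == pytest.approx(analytic, rel=0.05)

    def test_cage_matches_analytic_cavity(self):
        closed, _, truth = make_breathing_cage(0.0)
        p = PocketDefinition(center=[0.0, 0, 0], radius=6.0, spacing=0.5)
        v = pocket_volume(closed, p)
        assert v == pytest.approx(truth.cavity_volume, rel=0.05)

    def test_rigid_transform_invariance_within_boundary_layer(self):
        from scipy.spatial.transform import Rotation

        closed, _, truth = make_breathing_cage(0.0)
        p = PocketDefinition(center=[0.0, 0, 0], radius=6.0, spacing=0.5)
        v0 = pocket_volume(closed, p)
        rot = Rotation.from_euler("xyz", [17, 33, -21], degrees=True).as_matrix()
        shift = np.array([3.3, -1.7, 0.9])
        moved = closed.copy()
        moved.coords = closed.coords @ rot.T + shift
        p2 = PocketDefinition(center=shift, radius=6.0, spacing=0.5)
        v1 = pocket_volume(moved, p2)
        # tolerance: a one-grid-cell-thick layer over the cavity surface
        r_eff = (3 * v0 / (4 * np.pi)) ** (1 / 3)
        layer = 4 * np.pi * r_eff**2 * p.spacing
        assert abs(v1 - v0) <= layer

    def test_grid_refinement_converges(self):
        closed, _, truth = make_breathing_cage(0.0)
        vols = {}
        for delta in (1.0, 0.5, 0.25):
            p = PocketDefinition(center=[0.0, 0, 0], radius=6.0, spacing=delta)
            vols[delta] = pocket_volume(closed, p)
        assert abs(vols[0.5] - vols[0.25]) < abs(vols[1.0] - vols[0.5]) + 1e-9

    def test_volume_non_increasing_when_atoms_added(self):
        closed, _, _ = make_breathing_cage(0.0)
        p = PocketDefinition(center=[0.0, 0, 0], radius=6.0, spacing=0.5)
        v0 = pocket_volume(closed, p)
        # extra atom carves into the cavity edge without covering the seed
        both = Structure.from_atoms(
            [(closed.chains[i], closed.res_nums[i], closed.res_names[i],
              closed.atom_names[i], closed.elements[i], closed.coords[i])
             for i in range(len(closed))]
            + [("B", 1000, "DUM", "C1", "C", [0.0, 0.0, 2.95])]
        )
        assert pocket_volume(both, p) < v0

    def test_closed_pocket_seed_error_and_fallback(self):
        s = Structure.from_atoms([("A", 1, "DUM", "C1", "C", [0.0, 0, 0])])
        p = PocketDefinition(center=[0.0, 0, 0], radius=4.0, spacing=0.5)
        with pytest.raises(StructureError):
            pocket_volume(s, p)
        assert pocket_volume(s, p, allow_closed=True) == 0.0


class TestVolumeProfile:
    def test_constant_trajectory_constant_profile(self):
        closed, _, _ = make_breathing_cage(0.0)
        traj = MorphTrajectory([closed] * 4, np.linspace(0, 1, 4))
        p = PocketDefinition(center=[0.0, 0, 0], radius=6.0, spacing=0.5)
        prof = volume_profile(traj, p)
        assert prof.expansion == 0.0
        assert len(set(prof.volumes.tolist())) == 1

    def test_opening_cage_monotone_in_gate_displacement(self):
        p = PocketDefinition(center=[0.0, 0, 0], radius=8.0, spacing=0.5)
        vols = []
        for g in (0.0, 0.5, 1.0, 2.0):
            _, opened, _ = make_breathing_cage(g)
            vols.append(pocket_volume(opened, p))
        assert all(b >= a for a, b in zip(vols, vols[1:]))
        assert vols[-1] > vols[0]

    def test_morph_profile_with_glycine_substitution(self):
        # a target residue whose side chain fills the cavity while its
        # backbone sits outside the cage: after the per-frame glycine
        # substitution the frame-0 pocket equals the bare cage volume
        closed, opened, truth = make_breathing_cage(1.0)

        def with_target(cage):
            atoms = [(cage.chains[i], cage.res_nums[i], cage.res_names[i],
                      cage.atom_names[i], cage.elements[i], cage.coords[i])
                     for i in range(len(cage))]
            atoms += [
                ("T", 526, "TYR", "N", "N", [7.5, 0.0, 0.0]),
                ("T", 526, "TYR", "CA", "C", [8.5, 0.0, 0.0]),
                ("T", 526, "TYR", "C", "C", [9.5, 0.0, 0.0]),
                ("T", 526, "TYR", "O", "O", [10.0, 1.0, 0.0]),
                ("T", 526, "TYR", "CB", "C", [0.0, 0.0, 0.5]),
                ("T", 526, "TYR", "CG", "C", [0.0, 0.0, -0.5]),
            ]
            return Structure.from_atoms(atoms)

        traj = linear_morph(with_target(closed), with_target(opened),
                            n_frames=3, do_superpose=False)
        p = PocketDefinition(center=[0.0, 0, 0], radius=6.0, spacing=0.5)
        prof = volume_profile(traj, p, glycine_target=526, chain="T")
        bare = pocket_volume(closed, p)
        assert prof.volumes[0] == pytest.approx(bare)
        # without the substitution the side chain closes the pocket
        assert pocket_volume(with_target(closed), p, allow_closed=True) == 0.0


def test_ring_centroid_uses_ring_atoms():
    s = tyrosine_full()
    c = ring_centroid(s, 526)
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    expected = np.mean([s.atom_coord(526, n) for n in names], axis=0)
    np.testing.assert_allclose(c, expected)
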