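"""Structure model, PDB I/O and geometry primitives."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import protqa as pq
from protqa.errors import EmptyStructureError, GeometryError, SuperpositionError
from protqa.structure import backbone_dihedrals, dihedral, side_chain_chis, superpose

from conftest import random_rotation

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   SER A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA ASER A   2       3.988   2.832   0.000  0.60  0.00           C
ATOM      7  CA BSER A   2       3.988   2.832   0.500  0.40  0.00           C
ATOM      8  C   SER A   2       5.500   2.700   0.100  1.00  0.00           C
ATOM      9  O   SER A   2       6.100   1.650   0.200  1.00  0.00           O
ATOM     10  N   GLY A   3       6.120   3.870   0.100  1.00  0.00           N
ATOM     11  CA  GLY A   3       7.560   4.000   0.200  1.00  0.00           C
ATOM     12  C   GLY A   3       8.200   5.380   0.200  1.00  0.00           C
ATOM     13  O   GLY A   3       7.520   6.400   0.300  1.00  0.00           O
HETATM   14  O   HOH A   4      10.000  10.000  10.000  1.00  0.00           O
END
"""


class TestReadPdb:
    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(ALTLOC_PDB)
        st = pq.read_pdb(p)
        ca = st.residues[1].coord("CA")
        assert ca[2] == pytest.approx(0.0)  # altloc A (occ 0.60) wins

    def test_hetatm_water_dropped(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(ALTLOC_PDB)
        st = pq.read_pdb(p)
        assert st.n_residues == 3
        assert all(r.aa != "HOH" for r in st.residues)

    def test_no_standard_residues_raises(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text("HETATM    1  O   HOH A   1       0.000   0.000   0.000"
                     "  1.00  0.00           O\nEND\n")
        with pytest.raises(EmptyStructureError):
            pq.read_pdb(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(Exception):
            pq.read_pdb(tmp_path / "nope.pdb")


class TestWritePdb:
    def test_round_trip_preserves_structure(self, tmp_path, ideal_helix):
        p = tmp_path / "helix.pdb"
        pq.write_pdb(ideal_helix, p)
        back = pq.read_pdb(p)
        assert back.n_residues == ideal_helix.n_residues
        for r1, r2 in zip(ideal_helix.residues, back.residues):
            assert sorted(r1.atoms) == sorted(r2.atoms)
            for name in r1.atoms:
                np.testing.assert_allclose(
                    r1.coord(name), r2.coord(name), atol=1e-3)

    def test_two_chains_two_ter_records(self, tmp_path, ideal_helix):
        st = ideal_helix.copy()
        other = pq.build_chain("GGG", (-57.0, -47.0), chain_id="B")
        for res in other.residues:
            st.add_residue(res)
        p = tmp_path / "two.pdb"
        pq.write_pdb(st, p)
        assert p.read_text().count("TER") == 2

    def test_coordinate_formatting(self, tmp_path):
        st = pq.build_chain("A", (-57.0, -47.0))
        for _, atom in st.atoms():
            atom.coord = atom.coord + np.array([123.4567, 0, 0])
        p = tmp_path / "fmt.pdb"
        pq.write_pdb(st, p)
        assert " 123.457" in p.read_text()


class TestDihedral:
    def test_constructed_60_degrees(self):
        p4 = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 1.0])
        ang = dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], p4)
        assert ang == pytest.approx(60.0, abs=1e-9)

    def test_cis_is_zero(self):
        ang = dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [1, 0, 1])
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        ang = dihedral([1, 0, 0], [0, 0, 0], [0, 0, 1], [-1, 0, 1])
        assert ang == pytest.approx(180.0, abs=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_matches_canonical_frame_oracle(self, rng):
        """100 random quadruples vs an independent rotate-to-frame oracle."""
        for _ in range(100):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                ours = dihedral(*pts)
            except GeometryError:
                continue
            assert ours == pytest.approx(_frame_oracle(pts), abs=1e-9)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(size=(4, 3)) * 2.0
        ref = dihedral(*pts)
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.normal(size=3) * 10
            moved = pts @ R.T + t
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)


def _frame_oracle(pts: np.ndarray) -> float:
    """Rotate the quadruple so the central bond is +z, then read the
    torsion as the difference of azimuths."""
    p1, p2, p3, p4 = pts
    axis = p3 - p2
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    q = rot.apply(pts - p2)
    u = q[0] - q[1]
    v = q[3] - q[2]
    a1 = np.arctan2(u[1], u[0])
    a2 = np.arctan2(v[1], v[0])
    ang = np.degrees(a2 - a1)
    ang = (ang + 180.0) % 360.0 - 180.0
    return 180.0 if ang == -180.0 else ang


class TestBackboneDihedrals:
    def test_helix_round_trip(self, ideal_helix):
        tors = backbone_dihedrals(ideal_helix)
        for t in tors[1:-1]:
            assert t.phi == pytest.approx(-57.0, abs=1e-6)
            assert t.psi == pytest.approx(-47.0, abs=1e-6)

    def test_termini_undefined(self, ideal_helix):
        tors = backbone_dihedrals(ideal_helix)
        assert tors[0].phi is None
        assert tors[-1].psi is None

    def test_chain_break_undefines_cross_gap(self, ideal_helix):
        broken = ideal_helix.copy()
        for res in broken.residues[15:]:
            for atom in res.atoms.values():
                atom.coord = atom.coord + np.array([10.0, 0.0, 0.0])
        tors = backbone_dihedrals(broken)
        assert tors[15].phi is None and tors[15].omega is None
        assert tors[14].psi is None


class TestSideChainChis:
    def test_ala_has_no_chis(self):
        st = pq.build_chain("AAA", (-57.0, -47.0))
        assert side_chain_chis(st.residues[1]) == []

    def test_ser_constructed_chi1(self):
        st = pq.build_chain("SSS", (-57.0, -47.0), chi1=[65.0] * 3)
        chis = side_chain_chis(st.residues[1])
        assert len(chis) == 1
        assert chis[0] == pytest.approx(65.0, abs=1e-6)

    def test_missing_atom_truncates(self, mixed_native):
        # built side chains carry only CB + the chi1 partner
        for res in mixed_native.residues:
            chis = side_chain_chis(res)
            assert len(chis) <= 1


class TestSuperpose:
    def test_exact_rigid_copy_zero_rmsd(self, rng):
        A = rng.normal(size=(15, 3)) * 5
        R = random_rotation(rng)
        B = A @ R.T + np.array([1.0, -2.0, 3.0])
        sup = superpose(A, B)
        assert sup.rmsd < 1e-9
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_identity_on_self(self, rng):
        A = rng.normal(size=(10, 3))
        sup = superpose(A, A)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, 0.0, atol=1e-9)

    def test_beats_random_rotations(self, rng):
        """Kabsch rmsd is minimal: no random rotation does better."""
        A = rng.normal(size=(20, 3)) * 4
        B = A + rng.normal(scale=1.0, size=(20, 3))
        best = superpose(A, B).rmsd
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        rots = Rotation.random(10_000, rng=np.random.default_rng(7)).as_matrix()
        rotated = np.einsum("rij,nj->rni", rots, Ac)
        rmsds = np.sqrt(((rotated - Bc) ** 2).sum(axis=(1, 2)) / len(A))
        assert best <= rmsds.min() + 1e-12

    def test_swap_symmetry(self, rng):
        A = rng.normal(size=(12, 3))
        B = A + rng.normal(scale=0.5, size=(12, 3))
        assert superpose(A, B).rmsd == pytest.approx(superpose(B, A).rmsd, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(SuperpositionError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
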