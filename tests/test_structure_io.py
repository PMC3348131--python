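"""Structure parsing, cleanup, superposition and annotated write-out."""

import numpy as np
import pytest

from ensemblepockets import structure_io as sio

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      10.000   5.000   3.000  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.200   5.500   3.500  1.00 20.00           C
ATOM      3  N   GLY A   2      12.500   6.000   4.000  1.00 20.00           N
END
"""

ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1      10.000   5.000   3.000  1.00 20.00           C
ATOM      2  CB AALA A   1      11.000   5.000   3.000  0.60 20.00           C
ATOM      3  CB BALA A   1      11.500   5.500   3.500  0.40 20.00           C
END
"""

MIXED_PDB = """\
ATOM      1  N   ALA A   1      10.000   5.000   3.000  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.200   5.500   3.500  1.00 20.00           C
ATOM      3  CB  ALA A   1      11.800   4.500   4.300  1.00 20.00           C
ATOM      4  HB1 ALA A   1      12.100   4.900   5.100  1.00 20.00           H
ATOM      5  C   ALA A   1      12.300   6.200   2.800  1.00 20.00           C
ATOM      6  O   ALA A   1      13.000   7.000   3.300  1.00 20.00           O
HETATM    7  O   HOH A 101      20.000  20.000  20.000  1.00 30.00           O
HETATM    8  O   HOH A 102      22.000  20.000  20.000  1.00 30.00           O
END
"""


class TestParsePdb:
    def test_three_atom_transcription(self):
        s = sio.parse_pdb(THREE_ATOM_PDB)
        assert s.n_atoms == 3
        assert [a.atom_name for a in s.atoms] == ["N", "CA", "N"]
        assert len(s.residues) == 2
        np.testing.assert_allclose(s.atoms[1].position, (11.2, 5.5, 3.5))

    def test_missing_chain_raises(self):
        with pytest.raises(sio.ChainNotFoundError):
            sio.parse_pdb(THREE_ATOM_PDB, chain="B")

    def test_no_atoms_raises(self):
        with pytest.raises(sio.PDBError):
            sio.parse_pdb("REMARK nothing here\nEND\n")

    def test_altloc_keeps_highest_occupancy(self):
        s = sio.parse_pdb(ALTLOC_PDB)
        cb = [a for a in s.atoms if a.atom_name == "CB"]
        assert len(cb) == 1
        assert cb[0].occupancy == pytest.approx(0.6, abs=1e-6)
        np.testing.assert_allclose(cb[0].position, (11.0, 5.0, 3.0))

    def test_altloc_tie_keeps_first_listed(self):
        tie = ALTLOC_PDB.replace("0.60", "0.50").replace("0.40", "0.50")
        s = sio.parse_pdb(tie)
        cb = [a for a in s.atoms if a.atom_name == "CB"]
        assert len(cb) == 1
        np.testing.assert_allclose(cb[0].position, (11.0, 5.0, 3.0))


class TestStripHeteroatoms:
    def test_removes_waters_and_hydrogens(self):
        s = sio.strip_heteroatoms(sio.parse_pdb(MIXED_PDB))
        assert s.n_atoms == 5  # 6 protein atoms minus 1 hydrogen
        assert all(a.residue_name == "ALA" for a in s.atoms)
        assert all(a.element != "H" for a in s.atoms)

    def test_only_waters_raises(self):
        water_only = "\n".join(
            ln for ln in MIXED_PDB.splitlines() if ln.startswith(("HETATM", "END"))
        )
        with pytest.raises(sio.EmptyStructureError):
            sio.strip_heteroatoms(sio.parse_pdb(water_only))


def _kabsch_oracle(mobile, reference):
    """Independent least-squares fit: classic SVD Kabsch, coded from scratch."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = P @ R.T + reference.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))


class TestSuperpose:
    def test_self_superposition_is_zero(self, helix_bundle):
        _, rmsd = sio.superpose(helix_bundle, helix_bundle)
        assert rmsd < 1e-9

    def test_translation_removed(self, helix_bundle):
        moved = helix_bundle.with_coordinates(helix_bundle.coordinates() + [5, 0, 0])
        _, rmsd = sio.superpose(moved, helix_bundle)
        assert rmsd < 1e-9

    def test_noisy_rmsd_matches_independent_kabsch(self, helix_bundle, rng):
        coords = helix_bundle.coordinates()
        noisy = helix_bundle.with_coordinates(coords + rng.normal(0, 0.5, coords.shape))
        _, rmsd = sio.superpose(noisy, helix_bundle, selection=None)
        oracle = _kabsch_oracle(noisy.coordinates(), coords)
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_idempotent(self, helix_bundle, rng):
        coords = helix_bundle.coordinates()
        noisy = helix_bundle.with_coordinates(coords + rng.normal(0, 0.5, coords.shape))
        once, r1 = sio.superpose(noisy, helix_bundle)
        twice, r2 = sio.superpose(once, helix_bundle)
        assert abs(r1 - r2) < 1e-9

    def test_superposition_never_increases_rmsd(self, helix_bundle, rng):
        """For random rigid motions, the fitted RMSD is <= the unfitted one."""
        coords = helix_bundle.coordinates()
        ca = helix_bundle.select("CA")
        from scipy.spatial.transform import Rotation

        for _ in range(100):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0, 10, 3)
            moved = helix_bundle.with_coordinates(coords @ R.T + t)
            before = np.sqrt(np.mean(np.sum(
                (moved.coordinates()[ca] - coords[ca]) ** 2, axis=1)))
            _, after = sio.superpose(moved, helix_bundle)
            assert after <= before + 1e-9
            assert after < 1e-6  # rigid motion is removed exactly

    def test_selection_mismatch_raises(self, helix_bundle):
        sub = sio.MolecularStructure(helix_bundle.atoms[:10])
        with pytest.raises(ValueError, match="mismatch"):
            sio.superpose(sub, helix_bundle)

    def test_underdetermined_raises(self):
        s = sio.parse_pdb(THREE_ATOM_PDB)
        with pytest.raises(ValueError, match="at least 3"):
            sio.superpose(s, s, selection="CA")


class TestWritePdb:
    def test_round_trip_preserves_structure(self, helix_bundle):
        text = sio.write_pdb(helix_bundle)
        back = sio.parse_pdb(text)
        assert back.n_atoms == helix_bundle.n_atoms
        assert [a.atom_name for a in back.atoms] == \
            [a.atom_name for a in helix_bundle.atoms]
        assert back.residues == helix_bundle.residues
        np.testing.assert_allclose(
            back.coordinates(), helix_bundle.coordinates(), atol=1e-3
        )

    def test_round_trip_is_stable(self, helix_bundle):
        """parse(write(parse(x))) == parse(x) on names, keys and coordinates."""
        once = sio.parse_pdb(sio.write_pdb(helix_bundle))
        twice = sio.parse_pdb(sio.write_pdb(once))
        assert twice.residues == once.residues
        np.testing.assert_array_equal(twice.coordinates(), once.coordinates())

    def test_residue_values_written_to_all_atoms(self):
        s = sio.parse_pdb(MIXED_PDB)
        key = s.residues[0]
        back = sio.parse_pdb(sio.write_pdb(s, residue_values={key: 0.92}))
        for a in back.atoms:
            if a.residue_key == key:
                assert a.b_factor == pytest.approx(0.92, abs=1e-6)

    def test_no_values_preserves_b_factors(self):
        s = sio.parse_pdb(THREE_ATOM_PDB)
        back = sio.parse_pdb(sio.write_pdb(s))
        assert all(a.b_factor == pytest.approx(20.0) for a in back.atoms)

    def test_unknown_residue_key_raises(self):
        s = sio.parse_pdb(THREE_ATOM_PDB)
        with pytest.raises(KeyError):
            sio.write_pdb(s, residue_values={("Z", 99, "", "XXX"): 1.0})

    def test_out_of_range_value_raises(self):
        s = sio.parse_pdb(THREE_ATOM_PDB)
        with pytest.raises(ValueError, match="B-factor"):
            sio.write_pdb(s, residue_values={s.residues[0]: 123456.0})


class TestMultiModel:
    def test_models_round_trip(self, helix_bundle):
        coords = helix_bundle.coordinates()
        text = sio.write_multi_model_pdb(helix_bundle, [coords, coords + 1.0])
        assert text.count("MODEL") == 2
        assert text.count("ENDMDL") == 2
        back = sio.parse_pdb(text)  # first model
        np.testing.assert_allclose(back.coordinates(), coords, atol=1e-3)


class TestSpherePdb:
    def test_hetatm_positions_read(self):
        spheres = sio.read_sphere_pdb(MIXED_PDB)
        np.testing.assert_allclose(
            spheres, [[20.0, 20.0, 20.0], [22.0, 20.0, 20.0]]
        )

    def test_atom_records_used_when_no_hetatm(self):
        spheres = sio.read_sphere_pdb(THREE_ATOM_PDB)
        assert spheres.shape == (3, 3)
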