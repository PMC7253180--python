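"""Structure/trajectory I/O, selection language, and distance measurements."""

import numpy as np
import pytest

from confwire.structio import (
    AtomRecord,
    PDBFormatError,
    SelectionError,
    Structure,
    Trajectory,
    atom_distance,
    read_pdb,
    read_trajectory,
    resolve_selection,
    write_frames_xyz,
    write_multimodel_pdb,
    write_pdb,
)
from conftest import make_water, random_rigid

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)


class TestReadPDB:
    def test_minimal_atom_fields(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        s = read_pdb(p)
        assert len(s) == 1
        a = s.atoms[0]
        assert (a.name, a.resname, a.resid, a.chain, a.element) == ("CA", "ALA", 1, "A", "C")
        assert a.xyz == (1.0, 2.0, 3.0)

    def test_only_first_model_returned(self, tmp_path):
        text = "MODEL        1\n" + MINIMAL_PDB.replace("END\n", "ENDMDL\n")
        text += "MODEL        2\n" + MINIMAL_PDB.replace("1.000", "9.000").replace("END\n", "ENDMDL\nEND\n")
        p = tmp_path / "two_models.pdb"
        p.write_text(text)
        s = read_pdb(p)
        assert len(s) == 1
        assert s.atoms[0].xyz[0] == 1.0

    def test_altloc_b_dropped(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   2.000   3.000  1.00  0.00           C\n"
        )
        p = tmp_path / "altloc.pdb"
        p.write_text(text)
        s = read_pdb(p)
        assert len(s) == 1 and s.atoms[0].xyz[0] == 1.0

    def test_insertion_code_rejected(self, tmp_path):
        text = "ATOM      1  CA  ALA A   1A      1.000   2.000   3.000  1.00  0.00           C\n"
        p = tmp_path / "icode.pdb"
        p.write_text(text)
        with pytest.raises(PDBFormatError, match="insertion"):
            read_pdb(p)

    def test_zero_atoms_is_format_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PDBFormatError):
            read_pdb(p)

    def test_round_trip_preserves_records(self, tmp_path):
        rng = np.random.default_rng(7)
        atoms = []
        for i in range(10):
            resname = "HOH" if i % 3 == 0 else "GLY"
            atoms.append(
                AtomRecord(
                    i + 1,
                    "OH2" if resname == "HOH" else "CA",
                    "O" if resname == "HOH" else "C",
                    resname,
                    i + 1,
                    "A",
                    tuple(np.round(rng.uniform(-50, 50, 3), 3)),
                )
            )
        original = Structure(atoms)
        p = tmp_path / "rt.pdb"
        write_pdb(original, p)
        reread = read_pdb(p)
        assert len(reread) == 10
        for a, b in zip(original.atoms, reread.atoms):
            assert (a.serial, a.name, a.resname, a.resid, a.chain, a.element) == (
                b.serial, b.name, b.resname, b.resid, b.chain, b.element)
            assert np.allclose(a.xyz, b.xyz, atol=5e-4)  # PDB prints 3 decimals

    def test_parser_agrees_with_biotite(self, tmp_path):
        """Independent cross-check of the fixed-column parser."""
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        rng = np.random.default_rng(0)
        atoms = [
            AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A", tuple(np.round(rng.uniform(-99, 99, 3), 3)))
            for i in range(12)
        ]
        p = tmp_path / "x.pdb"
        write_pdb(Structure(atoms), p)
        ours = read_pdb(p)
        theirs = biotite_pdb.PDBFile.read(str(p)).get_structure(model=1)
        assert np.allclose(ours.coords, theirs.coord, atol=1e-6)
        assert [a.resid for a in ours.atoms] == list(theirs.res_id)
        assert [a.name for a in ours.atoms] == list(theirs.atom_name)


class TestTrajectory:
    def test_multimodel_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        atoms = [
            AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A", (0.0, 0.0, float(i))) for i in range(5)
        ]
        traj = Trajectory(Structure(atoms), np.round(rng.uniform(-20, 20, (3, 5, 3)), 3))
        p = tmp_path / "t.pdb"
        write_multimodel_pdb(traj, p)
        back = read_trajectory(p, dialect="multi-model-pdb")
        assert back.n_frames == 3 and len(back.topology) == 5
        assert np.allclose(back.frames, traj.frames, atol=5e-4)

    def test_frames_xyz_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        atoms = [
            AtomRecord(i + 1, "OW", "O", "HOH", i + 1, "A", (0.0, 0.0, 0.0)) for i in range(4)
        ]
        traj = Trajectory(Structure(atoms), rng.uniform(-9, 9, (100, 4, 3)))
        p = tmp_path / "t.frames"
        write_frames_xyz(traj, p, header_comments=["synthetic"])
        back = read_trajectory(p, dialect="frames-xyz")
        assert back.n_frames == 100
        assert np.allclose(back.frames, traj.frames, atol=1e-6)

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        text = "MODEL 1\n"
        text += "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        text += "ENDMDL\nMODEL 2\n"
        text += "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        text += "ATOM      2  CA  ALA A   2       4.000   2.000   3.000  1.00  0.00           C\n"
        text += "ENDMDL\n"
        p = tmp_path / "bad.pdb"
        p.write_text(text)
        with pytest.raises(PDBFormatError, match="atoms"):
            read_trajectory(p)


class TestSelection:
    def test_name_clause(self, gln_toy):
        sel = resolve_selection(gln_toy, "name CA")
        assert sel.indices == (0, 3)

    def test_resid_and_multi_name(self, gln_toy):
        sel = resolve_selection(gln_toy, "resid 148 and name OE1 NE2")
        assert sel.indices == (1, 2)

    def test_water_oxygen_count_matches_generator(self):
        waters = []
        for i in range(7):
            waters += make_water(i + 1, (3.0 * i, 0, 0), (3.0 * i + 0.96, 0, 0), serial0=3 * i + 1)
        s = Structure(waters)
        sel = resolve_selection(s, "resname HOH and name OH2")
        assert len(sel) == 7

    def test_or_and_ranges(self, gln_toy):
        sel = resolve_selection(gln_toy, "resid 148:148 or resid 149")
        assert len(sel) == 4

    def test_idempotent(self, gln_toy):
        expr = "resid 148 and name OE1 NE2"
        assert resolve_selection(gln_toy, expr) == resolve_selection(gln_toy, expr)

    def test_empty_result_allowed(self, gln_toy):
        assert len(resolve_selection(gln_toy, "resname TRP")) == 0

    @pytest.mark.parametrize("bad", ["resid", "flavor CA", "name CA and", "(name CA"])
    def test_syntax_errors(self, gln_toy, bad):
        with pytest.raises(SelectionError):
            resolve_selection(gln_toy, bad)


class TestAtomDistance:
    def _two_atoms(self):
        return Structure(
            [
                AtomRecord(1, "CA", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
                AtomRecord(2, "CA", "C", "ALA", 2, "A", (3.0, 4.0, 0.0)),
            ]
        )

    def test_three_four_five(self):
        s = self._two_atoms()
        assert atom_distance(s, "resid 1", "resid 2", mode="min") == pytest.approx(5.0)

    def test_same_selection_zero(self):
        s = self._two_atoms()
        assert atom_distance(s, "resid 1", "resid 1") == 0.0

    def test_centroid_hand_arithmetic(self):
        s = Structure(
            [
                AtomRecord(1, "CA", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
                AtomRecord(2, "CB", "C", "ALA", 1, "A", (2.0, 0.0, 0.0)),
                AtomRecord(3, "CA", "C", "ALA", 2, "A", (0.0, 3.0, 0.0)),
                AtomRecord(4, "CB", "C", "ALA", 2, "A", (2.0, 5.0, 0.0)),
            ]
        )
        # centroids (1,0,0) and (1,4,0) -> distance 4
        assert atom_distance(s, "resid 1", "resid 2", mode="centroid") == pytest.approx(4.0)

    def test_empty_selection_raises(self, gln_toy):
        with pytest.raises(ValueError):
            atom_distance(gln_toy, "resname TRP", "name CA")

    def test_symmetric_and_rigid_invariant(self, gln_toy):
        rng = np.random.default_rng(42)
        d0 = atom_distance(gln_toy, "resid 148", "resid 149")
        for _ in range(10):
            rot, trans = random_rigid(rng)
            moved = gln_toy.with_coords(gln_toy.coords @ rot.T + trans)
            d1 = atom_distance(moved, "resid 148", "resid 149")
            d2 = atom_distance(moved, "resid 149", "resid 148")
            assert d1 == pytest.approx(d0, abs=1e-9)
            assert d1 == pytest.approx(d2, abs=1e-12)
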