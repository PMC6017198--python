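import math

import numpy as np
import pytest

from rigiddg.structure import (AtomRecord, MutationSpec, PDBFormatError,
                               MutationMismatchError, ExternalToolRequiredError,
                               ResidueNotFoundError, SSRecord, Structure,
                               assign_secondary_structure, compute_sasa,
                               fibonacci_sphere, read_pdb, shrake_rupley,
                               truncate_to_glycine, write_pdb)
from rigiddg.synth import gen_toy_structure

ATOM_LINE = ("ATOM      1  CA  ALA A   1      11.104   6.134  -6.504"
             "  1.00 10.00           C")


def _residue_atoms(names, resname="LYS", resseq=1, chain="A", start_serial=1):
    rng = np.random.default_rng(0)
    return [AtomRecord(serial=start_serial + i, atom_name=n,
                       element=("H" if n.startswith("H") else n[0]),
                       residue_name=resname, chain_id=chain, residue_seq=resseq,
                       coords=rng.uniform(0, 5, 3))
            for i, n in enumerate(names)]


class TestReadWritePDB:
    def test_single_atom_fields_round_trip(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(ATOM_LINE + "\n")
        s = read_pdb(path)
        assert len(s) == 1
        a = s.atoms[0]
        assert (a.serial, a.atom_name, a.residue_name) == (1, "CA", "ALA")
        assert (a.chain_id, a.residue_seq) == ("A", 1)
        assert np.allclose(a.coords, [11.104, 6.134, -6.504])
        assert (a.occupancy, a.b_factor, a.element) == (1.0, 10.0, "C")

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(PDBFormatError, match="no ATOM records"):
            read_pdb(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "absent.pdb")

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("REMARK ok\nATOM  garbage\n")
        with pytest.raises(PDBFormatError, match="line 2"):
            read_pdb(path)

    def test_round_trip_preserves_atoms(self, tmp_path, helix):
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        write_pdb(helix, p1)
        s1 = read_pdb(p1)
        write_pdb(s1, p2)
        s2 = read_pdb(p2)
        assert len(s1) == len(s2) == len(helix)
        for a, b in zip(s1.atoms, s2.atoms):
            assert a.atom_name == b.atom_name
            assert np.array_equal(a.coords, b.coords)
        # coordinates survive the 8.3 fixed-point format to 5e-4 A
        for a, b in zip(helix.atoms, s1.atoms):
            assert np.all(np.abs(a.coords - b.coords) <= 5e-4)

    def test_coordinate_precision(self, tmp_path):
        a = AtomRecord(1, "CA", "C", "ALA", "A", 1, coords=[1.23456, 0, 0])
        path = tmp_path / "p.pdb"
        write_pdb(Structure(atoms=[a], id="x"), path)
        line = [l for l in path.read_text().splitlines() if l.startswith("ATOM")][0]
        assert line[30:38].strip() == "1.235"
        assert abs(read_pdb(path).atoms[0].coords[0] - 1.23456) <= 5e-4

    def test_two_chains_two_ter_records(self, tmp_path):
        atoms = (_residue_atoms(["N", "CA", "C", "O"], "GLY", 1, "A")
                 + _residue_atoms(["N", "CA", "C", "O"], "GLY", 1, "B", 5))
        path = tmp_path / "t.pdb"
        write_pdb(Structure(atoms=atoms, id="x"), path)
        lines = path.read_text().splitlines()
        assert sum(1 for l in lines if l.startswith("TER")) == 2
        assert lines[-1] == "END"

    def test_model_selection_and_hetatm_excluded(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(
            "MODEL        1\n" + ATOM_LINE + "\n"
            "HETATM    2  O   HOH A   2      0.000   0.000   0.000"
            "  1.00  0.00           O\nENDMDL\n"
            "MODEL        2\n"
            + ATOM_LINE.replace("11.104", "99.000") + "\nENDMDL\n")
        assert read_pdb(path).atoms[0].coords[0] == pytest.approx(11.104)
        assert read_pdb(path, model_index=1).atoms[0].coords[0] == pytest.approx(99.0)
        assert len(read_pdb(path)) == 1  # HETATM dropped

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        l1 = ATOM_LINE[:16] + "A" + ATOM_LINE[17:54] + "  0.30" + ATOM_LINE[60:]
        l2 = (ATOM_LINE[:16] + "B" + ATOM_LINE[17:30]
              + f"{9.0:8.3f}{6.134:8.3f}{-6.504:8.3f}" + "  0.70" + ATOM_LINE[60:])
        path = tmp_path / "alt.pdb"
        path.write_text(l1 + "\n" + l2 + "\n")
        s = read_pdb(path)
        assert len(s) == 1
        assert s.atoms[0].occupancy == pytest.approx(0.70)


class TestTruncateToGlycine:
    @pytest.mark.parametrize("resname,sidechain", [
        ("ALA", ["CB"]),
        ("LYS", ["CB", "CG", "CD", "CE", "NZ"]),
        ("GLY", []),
    ])
    def test_removes_exactly_the_side_chain(self, resname, sidechain):
        code = {"ALA": "A", "LYS": "K", "GLY": "G"}[resname]
        atoms = _residue_atoms(["N", "CA", "C", "O"] + sidechain, resname)
        s = Structure(atoms=atoms, id="x")
        out = truncate_to_glycine(s, MutationSpec("A", 1, code, "G"))
        assert len(s) - len(out) == len(sidechain)
        assert all(a.residue_name == "GLY" for a in out.atoms)
        assert len(s) == 4 + len(sidechain)  # input untouched

    def test_idempotent(self):
        s = Structure(atoms=_residue_atoms(["N", "CA", "C", "O", "CB"], "ALA"),
                      id="x")
        once = truncate_to_glycine(s, MutationSpec("A", 1, "A", "G"))
        twice = truncate_to_glycine(once, MutationSpec("A", 1, "G", "G"))
        assert [a.atom_name for a in once.atoms] == [a.atom_name for a in twice.atoms]

    def test_atom_count_conservation_on_helix(self, helix):
        out = truncate_to_glycine(helix, MutationSpec("A", 5, "A", "G"))
        sidechain = sum(1 for a in helix.atoms
                        if a.residue_seq == 5 and a.atom_name == "CB")
        assert len(helix) - len(out) == sidechain == 1

    def test_wt_mismatch_raises(self, helix):
        with pytest.raises(MutationMismatchError):
            truncate_to_glycine(helix, MutationSpec("A", 5, "K", "G"))

    def test_absent_residue_raises(self, helix):
        with pytest.raises(ResidueNotFoundError):
            truncate_to_glycine(helix, MutationSpec("A", 99, "A", "G"))

    def test_non_glycine_target_needs_external_tool(self, helix):
        with pytest.raises(ExternalToolRequiredError):
            truncate_to_glycine(helix, MutationSpec("A", 5, "A", "W"))


class TestSASA:
    def test_isolated_atom_matches_closed_form(self):
        r = 1.7
        area = shrake_rupley(np.zeros((1, 3)), np.array([r]), 1.4, 960)[0]
        assert area == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=1e-6)

    def test_fully_enclosed_atom_is_zero(self):
        shell = fibonacci_sphere(60) * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.7)
        assert shrake_rupley(coords, radii, 1.4, 960)[0] == 0.0

    def test_two_spheres_match_monte_carlo_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        radii = np.array([1.7, 1.52])
        got = shrake_rupley(coords, radii, 1.4, 960).sum()
        rng = np.random.default_rng(0)
        mc = 0.0
        for i in range(2):
            ri = radii[i] + 1.4
            v = rng.normal(size=(20000, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = coords[i] + ri * v
            j = 1 - i
            free = np.sum((pts - coords[j]) ** 2, axis=1) > (radii[j] + 1.4) ** 2
            mc += 4 * math.pi * ri * ri * free.mean()
        assert got == pytest.approx(mc, rel=0.02)

    def test_relative_sasa_bounded_and_referenced(self, helix):
        absolute, relative = compute_sasa(helix, ("A", 5))
        assert absolute >= 0
        assert 0 <= relative <= 100
        # Tien et al. ALA reference maximum
        assert relative == pytest.approx(100 * absolute / 129.0)

    def test_rigid_motion_invariance(self, helix):
        base, _ = compute_sasa(helix, ("A", 5))
        moved = helix.copy()
        c, s = math.cos(1.1), math.sin(1.1)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        for a in moved.atoms:
            a.coords = rot @ a.coords + np.array([7.0, -3.0, 11.0])
        shifted, _ = compute_sasa(moved, ("A", 5))
        assert abs(shifted - base) / base <= 0.005

    def test_absent_residue_raises(self, helix):
        with pytest.raises(ResidueNotFoundError):
            compute_sasa(helix, ("A", 42))


class TestSecondaryStructure:
    def test_header_record_takes_precedence(self, strand):
        s = strand.copy()
        s.ss_records = [SSRecord("helix", "A", 2, 6)]
        assert assign_secondary_structure(s, ("A", 3)) == "helix"
        assert assign_secondary_structure(s, ("A", 8)) == "sheet"  # fallback

    def test_no_record_no_fallback_gives_coil(self, helix):
        assert assign_secondary_structure(
            helix, ("A", 5), dihedral_fallback=False) == "coil"

    def test_dihedral_fallback_on_ideal_helix(self, helix):
        for pos in range(2, 10):
            assert assign_secondary_structure(helix, ("A", pos)) == "helix"

    def test_dihedral_fallback_on_extended_strand(self, strand):
        assert assign_secondary_structure(strand, ("A", 5)) == "sheet"

    def test_terminal_residue_defaults_to_coil(self, helix):
        assert assign_secondary_structure(helix, ("A", 1)) == "coil"
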