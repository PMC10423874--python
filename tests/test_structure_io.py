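import numpy as np
import pytest

from fodm import (EmptyUnitError, GeneratorConfig, ParseError,
                  UnknownResidueError, assign_hydrophobicity, effective_atom,
                  gen_unit, load_scale, load_structure, status_individual,
                  write_pdb)
from fodm.structure_io import ResidueModel

from conftest import make_unit, pdb_atom


class TestLoadStructure:
    def test_minimal_two_residue_file(self, minimal_pdb):
        unit = load_structure(minimal_pdb)
        assert len(unit) == 2
        assert [r.aa for r in unit.residues] == ["GLY", "ALA"]
        assert unit.chain_ids == ["A"]
        assert unit.ss_bonds == []
        # GLY falls back to CA; ALA uses its lone side-chain atom CB
        assert np.allclose(unit.residues[0].effective_xyz, [1.0, 0.0, 0.0])
        assert np.allclose(unit.residues[1].effective_xyz, [4.0, 1.5, 0.0])

    def test_first_model_only(self, tmp_path):
        lines = ["MODEL        1",
                 pdb_atom(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, element="C"),
                 "ENDMDL",
                 "MODEL        2",
                 pdb_atom(2, "CA", "GLY", "A", 1, 9.0, 9.0, 9.0, element="C"),
                 pdb_atom(3, "CA", "ALA", "A", 2, 8.0, 8.0, 8.0, element="C"),
                 "ENDMDL", "END"]
        p = tmp_path / "models.pdb"
        p.write_text("\n".join(lines) + "\n")
        unit = load_structure(p)
        assert len(unit) == 1
        assert np.allclose(unit.residues[0].effective_xyz, [0.0, 0.0, 0.0])

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        lines = [
            pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, element="C"),
            pdb_atom(2, "CB", "ALA", "A", 1, 1.0, 0.0, 0.0, element="C",
                     altloc="A", occ=0.3),
            pdb_atom(3, "CB", "ALA", "A", 1, 2.0, 0.0, 0.0, element="C",
                     altloc="B", occ=0.7),
            "END",
        ]
        p = tmp_path / "altloc.pdb"
        p.write_text("\n".join(lines) + "\n")
        unit = load_structure(p)
        assert np.allclose(unit.residues[0].effective_xyz, [2.0, 0.0, 0.0])

    def test_altloc_tie_keeps_first(self, tmp_path):
        lines = [
            pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, element="C"),
            pdb_atom(2, "CB", "ALA", "A", 1, 1.0, 0.0, 0.0, element="C",
                     altloc="A", occ=0.5),
            pdb_atom(3, "CB", "ALA", "A", 1, 2.0, 0.0, 0.0, element="C",
                     altloc="B", occ=0.5),
            "END",
        ]
        p = tmp_path / "tie.pdb"
        p.write_text("\n".join(lines) + "\n")
        unit = load_structure(p)
        assert np.allclose(unit.residues[0].effective_xyz, [1.0, 0.0, 0.0])

    def test_hetero_and_water_excluded(self, tmp_path):
        lines = [
            pdb_atom(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, element="C"),
            pdb_atom(2, "CA", "ALA", "A", 2, 4.0, 0.0, 0.0, element="C"),
            "HETATM    3  O   HOH A 101      9.000   9.000   9.000  1.00  0.00           O",
            "END",
        ]
        p = tmp_path / "het.pdb"
        p.write_text("\n".join(lines) + "\n")
        unit = load_structure(p)
        assert len(unit) == 2
        assert any("HOH" in s for s in unit.skipped)

    def test_mmcif_equivalent_to_pdb(self, tmp_path):
        import gemmi
        unit = gen_unit(GeneratorConfig(n_residues=20, seed=1))
        pdb_path = write_pdb(unit, tmp_path / "u.pdb")
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        st.make_mmcif_document().write_file(str(tmp_path / "u.cif"))
        from_cif = load_structure(tmp_path / "u.cif", format="mmcif")
        assert len(from_cif) == len(unit)
        assert np.allclose(from_cif.effective_coords(), unit.effective_coords())

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(ParseError):
            load_structure(tmp_path / "nope.pdb")

    def test_no_protein_residues_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HETATM    1  O   HOH A   1       0.000   0.000   0.000"
                     "  1.00  0.00           O\nEND\n")
        with pytest.raises(EmptyUnitError):
            load_structure(p)


class TestEffectiveAtom:
    def test_gly_falls_back_to_ca(self):
        r = ResidueModel("A", 1, "", "GLY",
                         atoms=[("N", "N", np.array([1.0, 0, 0])),
                                ("C", "CA", np.array([0.0, 0, 0])),
                                ("C", "C", np.array([2.0, 0, 0]))])
        assert np.allclose(effective_atom(r), [0.0, 0.0, 0.0])
        assert r.ca_fallback

    def test_single_side_chain_atom(self):
        r = ResidueModel("A", 1, "", "ALA",
                         atoms=[("C", "CA", np.array([0.0, 0, 0])),
                                ("C", "CB", np.array([1.0, 1, 1]))])
        assert np.allclose(effective_atom(r), [1.0, 1.0, 1.0])
        assert not r.ca_fallback

    def test_val_side_chain_centroid_by_hand(self):
        cb, cg1, cg2 = [1.0, 0.0, 0.0], [2.0, 1.0, 0.0], [2.0, -1.0, 3.0]
        r = ResidueModel("A", 1, "", "VAL",
                         atoms=[("C", "CA", np.zeros(3)),
                                ("C", "CB", np.array(cb)),
                                ("C", "CG1", np.array(cg1)),
                                ("C", "CG2", np.array(cg2))])
        expected = (np.array(cb) + np.array(cg1) + np.array(cg2)) / 3.0
        assert np.allclose(effective_atom(r), expected)

    def test_hydrogens_ignored(self):
        r = ResidueModel("A", 1, "", "ALA",
                         atoms=[("C", "CB", np.array([1.0, 1, 1])),
                                ("H", "HB1", np.array([9.0, 9, 9]))])
        assert np.allclose(effective_atom(r), [1.0, 1.0, 1.0])

    def test_no_side_chain_no_ca_raises(self):
        r = ResidueModel("A", 1, "", "ALA", atoms=[("N", "N", np.zeros(3))])
        with pytest.raises(ValueError):
            effective_atom(r)

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(0)
        atoms = [("C", n, rng.normal(size=3)) for n in ("CB", "CG", "CD")]
        r1 = ResidueModel("A", 1, "", "ARG", atoms=atoms)
        e1 = effective_atom(r1)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = np.array([5.0, -2.0, 1.0])
        r2 = ResidueModel("A", 1, "", "ARG",
                          atoms=[(el, n, xyz @ Q.T + t) for el, n, xyz in atoms])
        assert np.allclose(effective_atom(r2), e1 @ Q.T + t, atol=1e-12)


class TestHydrophobicity:
    def test_constant_scale(self):
        unit = make_unit([[0, 0, 0], [4, 0, 0]], aa="ALA")
        assign_hydrophobicity(unit, scale={aa: 1.0 for aa in
                                           ("ALA", "GLY", "VAL")})
        assert all(r.H == 1.0 for r in unit.residues)

    def test_min_max_rescaling_from_tsv(self, tmp_path):
        p = tmp_path / "scale.tsv"
        rows = {"ILE": 10.0, "ARG": -10.0}
        rows.update({aa: 0.0 for aa in
                     ("ALA", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
                      "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
                      "TYR", "VAL")})
        p.write_text("\n".join(f"{k}\t{v}" for k, v in rows.items()) + "\n")
        scale = load_scale(str(p))
        assert scale["ILE"] == 1.0 and scale["ARG"] == 0.0
        assert scale["ALA"] == pytest.approx(0.5)

    def test_mse_maps_to_met_under_lenient(self):
        unit = make_unit([[0, 0, 0]], aa="MSE")
        assign_hydrophobicity(unit, policy="lenient")
        met = load_scale()["MET"]
        assert unit.residues[0].H == pytest.approx(met)

    def test_unknown_code_strict_raises(self):
        unit = make_unit([[0, 0, 0]], aa="MSE")
        with pytest.raises(UnknownResidueError, match="MSE"):
            assign_hydrophobicity(unit, policy="strict")

    def test_idempotent_and_order_independent(self):
        unit = make_unit([[0, 0, 0], [4, 0, 0], [8, 0, 0]], aa="LEU")
        unit.residues[1].aa = "TRP"
        assign_hydrophobicity(unit)
        first = [r.H for r in unit.residues]
        assign_hydrophobicity(unit)
        assert [r.H for r in unit.residues] == first
        reordered = make_unit([[8, 0, 0], [4, 0, 0], [0, 0, 0]], aa="LEU")
        reordered.residues[1].aa = "TRP"
        assign_hydrophobicity(reordered)
        assert reordered.residues[1].H == first[1]


class TestWritePdb:
    def test_round_trip_preserves_everything(self, tmp_path):
        unit = gen_unit(GeneratorConfig(n_residues=40, seed=5))
        unit.ss_bonds = [(unit.residues[2].key, unit.residues[30].key)]
        path = write_pdb(unit, tmp_path / "u.pdb")
        text = path.read_text()
        assert text.count("SSBOND") == 1
        back = load_structure(path)
        assert len(back) == len(unit)
        assert [r.key for r in back.residues] == [r.key for r in unit.residues]
        assert [r.aa for r in back.residues] == [r.aa for r in unit.residues]
        assert back.ss_bonds == unit.ss_bonds
        assert np.allclose(back.effective_coords(), unit.effective_coords(),
                           atol=1e-3)

    def test_round_trip_rd_identical(self, tmp_path):
        unit = gen_unit(GeneratorConfig(n_residues=200, seed=3))
        rd0 = status_individual(unit)[0].rd
        back = load_structure(write_pdb(unit, tmp_path / "m.pdb"))
        assert status_individual(back)[0].rd == pytest.approx(rd0, abs=1e-6)

    def test_empty_unit_rejected(self, tmp_path):
        import fodm.structure_io as sio
        from fodm import StructureUnit
        with pytest.raises(ValueError):
            sio.write_pdb(StructureUnit(residues=[]), tmp_path / "e.pdb")

    def test_out_of_field_coordinates_rejected(self, tmp_path):
        unit = make_unit([[0, 0, 0], [123456.0, 0, 0]])
        with pytest.raises(ValueError, match="field width"):
            write_pdb(unit, tmp_path / "far.pdb")
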