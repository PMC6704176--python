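import numpy as np
import pytest

from rinsig.structio import (Atom, ComplexModel, ConfigError, PDBParseError,
                             Residue, StructureModel, assign_segments,
                             check_templates, normalize_segment_map,
                             read_pdb, write_pdb)
from rinsig.synthetic import build_peptide, build_toy_receptor


def small_model():
    return build_peptide(["ALA", "SER", "TYR"], chain_id="B")


class TestDomainTypes:
    def test_atom_validation(self):
        with pytest.raises(ValueError):
            Atom(serial=1, name="CA", element="C", coords=[0.0, 0.0])
        with pytest.raises(ValueError):
            Atom(serial=1, name="CA", element="C",
                 coords=[np.nan, 0.0, 0.0])
        a = Atom(serial=1, name="CA", element="C", coords=[1, 2, 3])
        assert a.mass == pytest.approx(12.011)

    def test_residue_rejects_duplicate_atom_names(self):
        a = Atom(serial=1, name="CA", element="C", coords=[0, 0, 0])
        b = Atom(serial=2, name="CA", element="C", coords=[1, 0, 0])
        with pytest.raises(ValueError, match="duplicate"):
            Residue(chain_id="A", seq_num=1, name="ALA", atoms=[a, b])

    def test_model_rejects_duplicate_residue_keys(self):
        def res():
            return Residue(chain_id="A", seq_num=1, name="ALA", atoms=[
                Atom(serial=1, name="CA", element="C", coords=[0, 0, 0])])
        with pytest.raises(ValueError, match="duplicate residue"):
            StructureModel(model_id=1, chains={"A": [res(), res()]})

    def test_copy_is_deep(self):
        m = small_model()
        c = m.copy()
        c.coords()
        first = next(c.atoms())
        first.coords[:] = 99.0
        assert not np.allclose(next(m.atoms()).coords, 99.0)

    def test_transformed_is_rigid(self):
        m = small_model()
        R = np.eye(3)
        t = np.array([5.0, -2.0, 1.0])
        moved = m.transformed(R, t)
        np.testing.assert_allclose(moved.coords(), m.coords() + t)

    def test_set_coords_shape_check(self):
        m = small_model()
        with pytest.raises(ValueError):
            m.set_coords(np.zeros((m.n_atoms + 1, 3)))

    def test_complex_partition(self):
        rec = build_toy_receptor()
        pep = build_peptide(["ALA", "ALA"], chain_id="P")
        st = StructureModel(model_id=1, chains={
            "A": rec.chains["A"], "P": pep.chains["P"]})
        cm = ComplexModel(structure=st, ligand_chain="P")
        assert {r.chain_id for r in cm.ligand_residues()} == {"P"}
        assert {r.chain_id for r in cm.receptor_residues()} == {"A"}
        assert all(r.segment == "LIGAND" for r in cm.ligand_residues())

    def test_complex_rejects_missing_ligand_chain(self):
        with pytest.raises(ValueError):
            ComplexModel(structure=small_model(), ligand_chain="Z")


class TestPDBRoundTrip:
    def test_roundtrip_preserves_structure(self, tmp_path):
        m = small_model()
        path = tmp_path / "m.pdb"
        write_pdb(m, path)
        back = read_pdb(path)[0]
        assert [r.key for r in back.residues()] \
            == [r.key for r in m.residues()]
        assert [a.name for a in back.atoms()] == [a.name for a in m.atoms()]
        # PDB coordinates are fixed-point with 3 decimals
        np.testing.assert_allclose(back.coords(), m.coords(), atol=1.5e-3)

    def test_roundtrip_nonstandard_residues(self, tmp_path):
        m = build_peptide("RI3", conformation="turn")
        path = tmp_path / "ri3.pdb"
        write_pdb(m, path)
        back = read_pdb(path)[0]
        assert [r.name for r in back.residues()] \
            == ["ACE", "DTY", "DAR", "AIB", "DAR", "NH2"]

    def test_multi_model(self, tmp_path):
        m1, m2 = small_model(), small_model()
        m2.set_coords(m2.coords() + 3.0)
        path = tmp_path / "multi.pdb"
        write_pdb([m1, m2], path)
        models = read_pdb(path, multi_model=True)
        assert len(models) == 2
        assert models[0].model_id == 1 and models[1].model_id == 2
        delta = models[1].coords() - models[0].coords()
        np.testing.assert_allclose(delta, 3.0, atol=1.5e-2)
        # default: first model only
        assert len(read_pdb(path)) == 1

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_pdb("/no/such/file.pdb")

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(PDBParseError):
            read_pdb(path)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.000   0.000   0.000"
            "  0.30  0.00           C\n"
            "ATOM      3  CA BALA A   1       2.000   0.000   0.000"
            "  0.70  0.00           C\n"
            "ATOM      4  C   ALA A   1       3.000   1.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      5  O   ALA A   1       3.500   2.000   0.000"
            "  1.00  0.00           O\n"
            "END\n")
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        model = read_pdb(path)[0]
        res = next(model.residues())
        assert res.atom("CA").coords[0] == pytest.approx(2.0)
        assert len(res.atoms) == 4

    def test_hydrogens_dropped(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  H   ALA A   1       0.500   0.500   0.000"
            "  1.00  0.00           H\n"
            "ATOM      3  CA  ALA A   1       1.400   0.000   0.000"
            "  1.00  0.00           C\n"
            "END\n")
        path = tmp_path / "h.pdb"
        path.write_text(pdb)
        model = read_pdb(path)[0]
        assert [a.name for a in model.atoms()] == ["N", "CA"]


class TestSegments:
    def test_normalize_accepts_all_formats(self):
        norm = normalize_segment_map({
            "TM1": "10-30", "TM2": [40, 60], "CTERM": ["70-80", "90-95"]})
        assert norm["TM1"] == [(10, 30)]
        assert norm["TM2"] == [(40, 60)]
        assert norm["CTERM"] == [(70, 80), (90, 95)]

    def test_rejects_unknown_label(self):
        with pytest.raises(ConfigError, match="unknown segment"):
            normalize_segment_map({"TM9": "1-10"})

    def test_rejects_overlap(self):
        with pytest.raises(ConfigError, match="overlap"):
            normalize_segment_map({"TM1": "10-30", "TM2": "25-40"})

    def test_rejects_inverted_range(self):
        with pytest.raises(ConfigError):
            normalize_segment_map({"TM1": "30-10"})

    def test_assign_segments(self):
        m = build_peptide(["ALA"] * 6, chain_id="A")
        out = assign_segments(m, {"TM1": "1-3", "CTERM": "5-6"})
        segs = [r.segment for r in out.residues()]
        assert segs == ["TM1", "TM1", "TM1", "UNASSIGNED", "CTERM",
                        "CTERM"]
        # original untouched
        assert all(r.segment == "UNASSIGNED" for r in m.residues())

    def test_assign_skips_ligand(self):
        rec = build_peptide(["ALA"] * 3, chain_id="A")
        pep = build_peptide(["ALA"], chain_id="P")
        st = StructureModel(model_id=1, chains={
            "A": rec.chains["A"], "P": pep.chains["P"]})
        cm = ComplexModel(structure=st, ligand_chain="P")
        out = assign_segments(cm.structure, {"TM1": "1-3"})
        assert out.residue(("P", 1, "")).segment == "LIGAND"


class TestTemplatesCheck:
    def test_clean_model_passes(self):
        check_templates(small_model())

    def test_unknown_residue_reported(self):
        m = small_model()
        list(m.residues())[0].name = "XYZ"
        with pytest.raises(ConfigError, match="XYZ"):
            check_templates(m)
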