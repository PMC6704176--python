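import numpy as np
import networkx as nx
import pytest

from rinsig.interactions import detect, detect_hbonds, detect_pi_cation
from rinsig.rama import backbone_dihedrals
from rinsig.rin import build_rin
from rinsig.structio import SEGMENTS, StructureModel
from rinsig.synthetic import (SEQUENCES, TOY_SEGMENT_MAP, agonist_complex,
                              antagonist_complex, build_helix,
                              build_peptide, build_toy_receptor,
                              parse_sequence, plant_interaction,
                              pocket_probe_complex)


class TestSequences:
    def test_named_presets(self):
        assert SEQUENCES["fMLF"] == ["FME", "LEU", "PHE"]
        assert SEQUENCES["RI3"][0] == "ACE" and SEQUENCES["RI3"][-1] == "NH2"

    def test_parse_three_letter_list(self):
        assert parse_sequence(["ala", "ARG"]) == ["ALA", "ARG"]

    def test_parse_named(self):
        assert parse_sequence("SRSRY") == SEQUENCES["SRSRY"]

    def test_unknown_residue_rejected_at_build(self):
        with pytest.raises((ValueError, KeyError)):
            build_peptide(["NOPE"])


class TestBuilders:
    def test_helix_dihedrals(self):
        h = build_helix(["ALA"] * 8)
        inner = backbone_dihedrals(h)[1:-1]
        for e in inner:
            assert e.phi == pytest.approx(-57.0, abs=1.0)
            assert e.psi == pytest.approx(-47.0, abs=1.0)

    def test_helix_mm_chain_connected(self):
        # the MM H-bond ladder of an ideal helix forms a connected chain
        h = build_helix(["ALA"] * 12)
        g = nx.Graph()
        for res in h.residues():
            g.add_node(res.key)
        for e in detect_hbonds(h):
            if e.hb_class == "MM":
                g.add_edge(e.key_a, e.key_b)
        assert nx.is_connected(g)

    def test_extended_dihedrals(self):
        p = build_peptide(["ALA"] * 6, conformation="extended")
        inner = backbone_dihedrals(p)[1:-1]
        for e in inner:
            assert e.phi == pytest.approx(-120.0, abs=1.0)
            assert e.psi == pytest.approx(120.0, abs=1.0)

    def test_turn_closes_co_nh_contact(self):
        p = build_peptide(["ALA"] * 4, conformation="turn")
        o1 = p.chains["P"][0].atom("O").coords
        n4 = p.chains["P"][3].atom("N").coords
        assert np.linalg.norm(o1 - n4) == pytest.approx(2.9, abs=0.5)

    def test_turn_needs_four_residues(self):
        with pytest.raises(ValueError, match="turn"):
            build_peptide(["ALA"] * 3, conformation="turn")

    def test_unknown_conformation(self):
        with pytest.raises(ValueError):
            build_peptide(["ALA"] * 4, conformation="zigzag")

    def test_d_residues_mirror(self):
        # D-Tyr side chain is the mirror image: same bond lengths,
        # opposite CB improper torsion sign vs L-Tyr
        lt = build_peptide(["GLY", "TYR", "GLY"])
        dt = build_peptide(["GLY", "DTY", "GLY"])
        lres = lt.chains["P"][1]
        dres = dt.chains["P"][1]
        from rinsig.geometry import dihedral_deg
        tl = dihedral_deg(lres.atom("N").coords, lres.atom("C").coords,
                          lres.atom("CA").coords, lres.atom("CB").coords)
        td = dihedral_deg(dres.atom("N").coords, dres.atom("C").coords,
                          dres.atom("CA").coords, dres.atom("CB").coords)
        assert tl == pytest.approx(-td, abs=1.0)

    def test_caps_present(self):
        p = build_peptide("RI3", conformation="turn")
        names = [r.name for r in p.residues()]
        assert names[0] == "ACE" and names[-1] == "NH2"
        assert p.chains["P"][0].atom("O") is not None
        assert p.chains["P"][-1].atom("N") is not None

    def test_fme_formyl_atoms(self):
        p = build_peptide("fMLF")
        fme = p.chains["P"][0]
        assert fme.atom("CN") is not None and fme.atom("O1") is not None


class TestConformationContracts:
    def test_fmlf_extended_no_mm(self):
        p = build_peptide("fMLF", conformation="extended")
        assert not [e for e in detect_hbonds(p) if e.hb_class == "MM"]

    def test_ri3_turn_co1_nh4(self):
        p = build_peptide("RI3", conformation="turn")
        mm = [e for e in detect_hbonds(p) if e.hb_class == "MM"]
        # CO of D-Tyr (seq 2, first residue after the cap) accepts from
        # NH of the second D-Arg (seq 5): the i -> i+3 turn closure
        assert any(e.res_b.seq_num == 2 and e.res_a.seq_num == 5
                   and e.atoms_b[0] in ("O", "O1") and e.atoms_a[0] == "N"
                   for e in mm)

    def test_srsry_turn_both_closures(self):
        p = build_peptide("SRSRY", conformation="turn")
        mm = [(e.res_b.seq_num, e.res_a.seq_num)
              for e in detect_hbonds(p) if e.hb_class == "MM"
              and e.atoms_a[0] == "N" and e.atoms_b[0] in ("O", "O1")]
        assert (1, 4) in mm and (1, 5) in mm


class TestToyReceptor:
    def test_segment_annotation(self, toy_receptor):
        segs = {r.segment for r in toy_receptor.residues()}
        assert {f"TM{i}" for i in range(1, 8)} <= segs
        assert "CTERM" in segs
        assert segs <= SEGMENTS

    def test_special_residues_in_place(self, toy_receptor):
        assert toy_receptor.residue(("A", 81, "")).name == "PHE"
        assert toy_receptor.residue(("A", 85, "")).name == "LYS"
        assert toy_receptor.residue(("A", 287, "")).name == "SER"
        assert toy_receptor.residue(("A", 328, "")).name == "SER"

    def test_segment_map_export(self):
        assert set(TOY_SEGMENT_MAP) \
            == {f"TM{i}" for i in range(1, 8)} | {"CTERM"}

    def test_pocket_narrows_downward(self, toy_receptor):
        coords = toy_receptor.coords()
        z = coords[:, 2]
        top = coords[z > z.max() - 3.0]
        bottom = coords[(z > z.min() + 18.0) & (z < z.min() + 21.0)]
        r_top = np.hypot(top[:, 0], top[:, 1]).mean()
        r_bot = np.hypot(bottom[:, 0], bottom[:, 1]).mean()
        assert r_top > r_bot


class TestPlanting:
    def test_plant_each_kind(self, toy_receptor):
        pep = build_peptide("SRSRY", conformation="turn")
        st = StructureModel(model_id=1, chains={
            "A": toy_receptor.copy().chains["A"],
            "P": pep.chains["P"]})
        for res in st.chains["P"]:
            for a in res.atoms:
                a.coords = a.coords + np.array([0.0, 0.0, 40.0])
        lig_keys = [r.key for r in st.chains["P"]]
        planted = plant_interaction(
            st, "hbond", (("A", 287, ""), ("P", 1, "")), 3.0,
            move_group=lig_keys)
        from rinsig.structio import ComplexModel
        cm = ComplexModel(structure=planted, ligand_chain="P")
        edges = [e for e in detect("hbond", cm)
                 if {e.key_a, e.key_b} == {("A", 287, ""), ("P", 1, "")}]
        assert edges and min(abs(e.distance - 3.0) for e in edges) < 0.06

    def test_plant_rejects_distance_beyond_cutoff(self, toy_receptor):
        pep = build_peptide("SRSRY")
        st = StructureModel(model_id=1, chains={
            "A": toy_receptor.copy().chains["A"],
            "P": pep.chains["P"]})
        with pytest.raises(ValueError, match="cutoff"):
            plant_interaction(st, "hbond", (("A", 287, ""), ("P", 1, "")),
                              5.0)

    def test_plant_unknown_kind(self, toy_receptor):
        pep = build_peptide("SRSRY")
        st = StructureModel(model_id=1, chains={
            "A": toy_receptor.copy().chains["A"],
            "P": pep.chains["P"]})
        with pytest.raises(ValueError):
            plant_interaction(st, "hydrophobic",
                              (("A", 287, ""), ("P", 1, "")), 3.0)


class TestPresets:
    def test_agonist_reproducible(self):
        a = agonist_complex(seed=5)
        b = agonist_complex(seed=5)
        np.testing.assert_array_equal(a.structure.coords(),
                                      b.structure.coords())

    def test_antagonist_no_receptor_hbond(self, antagonist):
        lig = {r.key for r in antagonist.ligand_residues()}
        for e in detect_hbonds(antagonist):
            assert (e.key_a in lig) == (e.key_b in lig)

    def test_antagonist_cation_pi_to_anchor(self, antagonist):
        lig = {r.key for r in antagonist.ligand_residues()}
        cross = [e for e in detect_pi_cation(antagonist)
                 if (e.key_a in lig) != (e.key_b in lig)]
        assert any(e.res_a.seq_num == 85 for e in cross)

    def test_agonist_network_reaches_cterm(self, agonist):
        net = build_rin(agonist)
        segs = {rin_node.segment for rin_node in net.nodes}
        assert "CTERM" in segs and "LIGAND" in segs

    def test_probe_noise_free_by_default(self):
        a = pocket_probe_complex()
        b = pocket_probe_complex()
        np.testing.assert_array_equal(a.structure.coords(),
                                      b.structure.coords())
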