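import numpy as np
import pytest

from rinsig.geometry import random_rigid_transform
from rinsig.interactions import Cutoffs
from rinsig.pocket import (PocketProfile, check_single_occupancy,
                           peptide_extent, profile_pocket, rank_poses,
                           score_pose)
from rinsig.structio import ComplexModel, StructureModel
from rinsig.synthetic import (build_peptide, build_toy_receptor,
                              pocket_probe_complex)


class TestProfile:
    def test_probe_recovers_cone_dimensions(self, probe):
        prof = profile_pocket(probe)
        # built with mouth radius 8 and depth 13; the lining-centroid
        # surrogate must land within 15 %
        assert prof.mouth_radius == pytest.approx(8.0, rel=0.15)
        assert prof.depth == pytest.approx(13.0, rel=0.15)
        assert prof.axis is not None and prof.has_dimensions
        # axis points tip -> mouth, i.e. roughly +z for the toy
        assert prof.axis[2] > 0.9

    def test_lining_is_receptor_only(self, probe):
        prof = profile_pocket(probe)
        assert all(r.chain_id == "A" for r in prof.lining)
        assert len(prof.lining) >= 10

    def test_chem_classes_recorded(self, probe):
        prof = profile_pocket(probe)
        counts = prof.class_counts()
        assert sum(counts.values()) == len(prof.lining)

    def test_explicit_lining(self, toy_receptor):
        residues = [toy_receptor.residue(("A", n, ""))
                    for n in range(78, 87)]
        prof = profile_pocket(lining=residues)
        assert prof.has_dimensions and prof.depth > 0

    def test_few_lining_warns(self, toy_receptor):
        residues = [toy_receptor.residue(("A", n, "")) for n in (81, 85)]
        with pytest.warns(UserWarning, match="lining"):
            prof = profile_pocket(lining=residues)
        assert not prof.has_dimensions

    def test_no_input_warns(self):
        with pytest.warns(UserWarning):
            prof = profile_pocket()
        assert prof.lining == []

    def test_rigid_invariance(self, probe):
        ref = profile_pocket(probe)
        rng = np.random.default_rng(5)
        for _ in range(3):
            R, t = random_rigid_transform(rng)
            moved = ComplexModel(
                structure=probe.structure.transformed(R, t),
                ligand_chain="P")
            prof = profile_pocket(moved)
            assert prof.depth == pytest.approx(ref.depth, abs=1e-6)
            assert prof.mouth_radius == pytest.approx(ref.mouth_radius,
                                                      abs=1e-6)

    def test_to_dict(self, probe):
        d = profile_pocket(probe).to_dict()
        assert set(d) >= {"lining", "depth", "mouth_radius", "axis"}


class TestOccupancy:
    def test_reported_dimensions_admit_one_peptide(self):
        # the documented qualitative argument: a cone of mouth radius 8
        # and depth 13 cannot hold two 14-Å peptides
        prof = PocketProfile(lining=[None] * 4, depth=13.0,
                             mouth_radius=8.0)
        assert check_single_occupancy(prof, 14.0) is True

    def test_large_pocket_fails(self):
        prof = PocketProfile(lining=[None] * 4, depth=30.0,
                             mouth_radius=8.0)
        assert check_single_occupancy(prof, 14.0) is False

    def test_strict_inequality(self):
        prof = PocketProfile(lining=[None] * 4, depth=14.0,
                             mouth_radius=8.0)
        assert check_single_occupancy(prof, 14.0) is False

    def test_requires_dimensions(self):
        with pytest.raises(ValueError):
            check_single_occupancy(PocketProfile(), 14.0)

    def test_probe_profile_vs_pentapeptide(self, probe):
        prof = profile_pocket(probe)
        srsry = build_peptide("SRSRY", conformation="turn")
        assert check_single_occupancy(
            prof, peptide_extent(srsry.chains["P"])) is True


class TestExtent:
    def test_extent_grows_with_length(self):
        short = build_peptide(["ALA"] * 2)
        long = build_peptide(["ALA"] * 6)
        assert peptide_extent(long.chains["P"]) \
            > peptide_extent(short.chains["P"])

    def test_single_atom(self):
        m = build_peptide(["ALA"])
        res = m.chains["P"][0]
        res.atoms = res.atoms[:1]
        assert peptide_extent([res]) == 0.0

    def test_rigid_invariant(self):
        m = build_peptide("SRSRY")
        ref = peptide_extent(m.chains["P"])
        rng = np.random.default_rng(1)
        R, t = random_rigid_transform(rng)
        moved = m.transformed(R, t)
        assert peptide_extent(moved.chains["P"]) == pytest.approx(ref)


def _pose_set():
    """The agonist preset plus weakened variants: fewer planted bonds
    and one pose far out of the groove."""
    from rinsig.synthetic import agonist_complex
    base = agonist_complex(seed=3, noise_sigma=0.0)
    poses = [base]
    # pose 1: ligand pushed 3 Å up (loses most H-bonds, keeps groove)
    up = base.structure.copy()
    for res in up.chains["P"]:
        for a in res.atoms:
            a.coords = a.coords + np.array([0.0, 0.0, 3.0])
    poses.append(ComplexModel(structure=up, ligand_chain="P"))
    # pose 2: ligand far outside the groove
    out = base.structure.copy()
    for res in out.chains["P"]:
        for a in res.atoms:
            a.coords = a.coords + np.array([40.0, 0.0, 0.0])
    poses.append(ComplexModel(structure=out, ligand_chain="P"))
    return poses


class TestPoses:
    def test_score_counts_interface(self):
        poses = _pose_set()
        s0 = score_pose(poses[0])
        assert s0.n_hbonds >= 2 and s0.in_groove
        assert s0.n_interface_residues > 0
        assert s0.total == s0.n_hbonds + s0.n_salt_bridges

    def test_ranking_rule(self):
        poses = _pose_set()
        scores = rank_poses(poses)
        ids = [s.pose_id for s in scores]
        assert 2 not in ids              # out-of-groove pose discarded
        assert ids[0] == 0               # most bonds wins
        assert [s.rank for s in scores] == list(range(1, len(scores) + 1))
        totals = [s.total for s in scores]
        assert totals == sorted(totals, reverse=True)

    def test_ranking_deterministic(self):
        a = [s.to_dict() for s in rank_poses(_pose_set())]
        b = [s.to_dict() for s in rank_poses(_pose_set())]
        assert a == b

    def test_tie_break_by_interface_then_id(self):
        # duplicated poses tie on every count: pose id breaks the tie
        poses = _pose_set()[:1] * 3
        scores = rank_poses(poses)
        assert [s.pose_id for s in scores] == [0, 1, 2]

    def test_empty(self):
        assert rank_poses([]) == []

    def test_bad_reference_index(self):
        with pytest.raises(ValueError, match="reference"):
            rank_poses(_pose_set(), reference_index=99)

    def test_custom_cutoffs(self):
        poses = _pose_set()
        loose = rank_poses(poses, cutoffs=Cutoffs(iac=12.0))
        assert loose  # still ranks under modified thresholds


def test_build_receptor_rejects_bad_args():
    with pytest.raises(ValueError):
        build_toy_receptor(n_helices=0)


def test_structure_model_import_sanity():
    assert StructureModel is not None
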