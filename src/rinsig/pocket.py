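"""Binding-pocket profiling and docking-pose ranking.

The pocket is defined by its lining: the receptor residues in contact
with the bound peptide (IAC edges), or an explicitly supplied list. A
seven-helix receptor pocket is roughly cone-shaped with the tip toward
the membrane; its dimensions are measured on the lining-residue
centroids — the cone axis as their principal axis, the depth as the
extent along it, and the mouth radius as the maximal radial distance at
the wide (extracellular) end. These are geometric surrogates, intended
for qualitative single-occupancy reasoning, not high-precision cavity
volumetrics.

Pose ranking reproduces the standard docking-selection recipe: discard
poses whose ligand is not in the binding groove, then rank by the
number of H-bonds plus salt bridges across the interface, breaking ties
by interface size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import get_template
from .geometry import principal_axis
from .interactions import (Cutoffs, detect_hbonds, detect_iac,
                           detect_salt_bridges)
from .structio import ComplexModel, Residue

#: fraction of the axial extent counted as the mouth end when measuring
#: the mouth radius
MOUTH_FRACTION = 0.25
#: default groove margin (Å) added around the pocket for the in-groove test
GROOVE_MARGIN = 2.0


@dataclass
class PocketProfile:
    lining: list[Residue] = field(default_factory=list)
    chem_classes: dict[tuple, str] = field(default_factory=dict)
    segments: dict[tuple, str] = field(default_factory=dict)
    depth: float | None = None        # Å, extent along the axis
    mouth_radius: float | None = None  # Å, at the wide end
    axis: np.ndarray | None = None    # unit vector, tip -> mouth
    origin: np.ndarray | None = None  # centroid of lining centroids
    axis_range: tuple[float, float] | None = None  # axial extent (t_min, t_max)

    @property
    def has_dimensions(self) -> bool:
        return self.depth is not None

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cls in self.chem_classes.values():
            out[cls] = out.get(cls, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "lining": [r.label for r in self.lining],
            "class_counts": self.class_counts(),
            "depth": None if self.depth is None else round(self.depth, 2),
            "mouth_radius": None if self.mouth_radius is None
            else round(self.mouth_radius, 2),
            "axis": None if self.axis is None
            else [round(x, 4) for x in self.axis],
        }


def profile_pocket(complex_model: ComplexModel | None = None,
                   iac_cutoff: float | None = None,
                   lining: list[Residue] | None = None) -> PocketProfile:
    """Profile the ligand-binding pocket.

    Lining residues are the receptor residues with an IAC contact to the
    ligand (or the explicit ``lining`` list). With fewer than 4 lining
    residues a warning profile without dimensions is returned.
    """
    if lining is None:
        if complex_model is None:
            warnings.warn("no ligand and no lining list; empty profile",
                          stacklevel=2)
            return PocketProfile()
        cut = Cutoffs() if iac_cutoff is None else Cutoffs(iac=iac_cutoff)
        iac_edges = detect_iac(complex_model, cutoffs=cut)
        seen: dict[tuple, Residue] = {}
        for e in iac_edges:
            seen.setdefault(e.res_b.key, e.res_b)
        lining = [seen[k] for k in sorted(seen)]
    profile = PocketProfile(lining=list(lining))
    for r in lining:
        profile.chem_classes[r.key] = get_template(r.name).chem_class
        profile.segments[r.key] = r.segment
    if len(lining) < 4:
        warnings.warn(
            f"only {len(lining)} lining residues; pocket dimensions unset",
            stacklevel=2)
        return profile
    centroids = np.array([r.centroid() for r in lining])
    # The pocket axis is where the peptide sits: use the ligand's
    # principal axis when a complex is given. For a wide cone the
    # principal axis of the lining centroids themselves is dominated by
    # the circular spread, so it is only the fallback for explicit
    # lining lists.
    if complex_model is not None:
        lig_coords = np.array([a.coords
                               for r in complex_model.ligand_residues()
                               for a in r.atoms])
        axis = principal_axis(lig_coords)
    else:
        axis = principal_axis(centroids)
    origin = centroids.mean(axis=0)
    t = (centroids - origin) @ axis
    radial = np.linalg.norm(
        (centroids - origin) - np.outer(t, axis), axis=1)
    # orient the axis tip -> mouth: the mouth (extracellular) end of a
    # cone is the wider one
    hi = t >= np.median(t)
    if radial[hi].mean() < radial[~hi].mean():
        axis = -axis
        t = -t
    t_min, t_max = float(t.min()), float(t.max())
    depth = t_max - t_min
    mouth_sel = t >= t_max - MOUTH_FRACTION * max(depth, 1e-9)
    profile.axis = axis
    profile.origin = origin
    profile.axis_range = (t_min, t_max)
    profile.depth = depth
    profile.mouth_radius = float(radial[mouth_sel].max())
    return profile


def check_single_occupancy(profile: PocketProfile,
                           peptide_length: float) -> bool:
    """True iff the pocket can hold only one peptide at a time: both the
    mouth radius and the depth are strictly smaller than the peptide
    length."""
    if not profile.has_dimensions:
        raise ValueError("profile has no dimensions")
    return (profile.mouth_radius < peptide_length
            and profile.depth < peptide_length)


def peptide_extent(ligand_residues: list[Residue]) -> float:
    """Maximum heavy-atom pairwise distance within the ligand (Å)."""
    coords = np.array([a.coords for r in ligand_residues for a in r.atoms])
    if len(coords) < 2:
        return 0.0
    # pairwise max via broadcasting; ligands are small
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    return float(d.max())


@dataclass
class PoseScore:
    pose_id: int
    n_interface_residues: int
    n_hbonds: int
    n_salt_bridges: int
    in_groove: bool
    rank: int | None = None   # assigned only to in-groove poses

    @property
    def total(self) -> int:
        return self.n_hbonds + self.n_salt_bridges

    def to_dict(self) -> dict:
        return {"pose_id": self.pose_id, "rank": self.rank,
                "in_groove": self.in_groove, "n_hbonds": self.n_hbonds,
                "n_salt_bridges": self.n_salt_bridges,
                "n_interface_residues": self.n_interface_residues}


def _ligand_centroid(complex_model: ComplexModel) -> np.ndarray:
    coords = np.array([a.coords for r in complex_model.ligand_residues()
                       for a in r.atoms])
    return coords.mean(axis=0)


def _in_groove(complex_model: ComplexModel, profile: PocketProfile,
               margin: float) -> bool:
    if not profile.has_dimensions:
        raise ValueError("groove test needs a profile with dimensions")
    c = _ligand_centroid(complex_model)
    rel = c - profile.origin
    t = float(rel @ profile.axis)
    radial = float(np.linalg.norm(rel - t * profile.axis))
    t_min, t_max = profile.axis_range
    return (radial <= profile.mouth_radius + margin
            and t_min - margin <= t <= t_max + margin)


def _interface_edges(complex_model: ComplexModel, cutoffs: Cutoffs):
    lig = {r.key for r in complex_model.ligand_residues()}

    def cross(edges):
        return [e for e in edges if (e.key_a in lig) != (e.key_b in lig)]

    hb = cross(detect_hbonds(complex_model, cutoffs=cutoffs))
    sb = cross(detect_salt_bridges(complex_model, cutoffs=cutoffs))
    iac = detect_iac(complex_model, cutoffs=cutoffs)
    return hb, sb, iac


def score_pose(complex_model: ComplexModel, pose_id: int = 0,
               cutoffs: Cutoffs | None = None,
               profile: PocketProfile | None = None,
               margin: float = GROOVE_MARGIN,
               include_ligand_residues: bool = False) -> PoseScore:
    """Score one docking pose.

    Interface counts are restricted to receptor-ligand edges; the
    in-groove flag tests the ligand centroid against the pocket cone
    (``profile``; computed from this pose itself when omitted). By
    default the interface size counts receptor residues only; set
    ``include_ligand_residues`` to count both sides.
    """
    cut = cutoffs or Cutoffs()
    if profile is None:
        profile = profile_pocket(complex_model, iac_cutoff=cut.iac)
    hb, sb, iac = _interface_edges(complex_model, cut)
    rec_iface = {e.key_b for e in iac}
    n_iface = len(rec_iface)
    if include_ligand_residues:
        n_iface += len({e.key_a for e in iac})
    in_groove = (_in_groove(complex_model, profile, margin)
                 if profile.has_dimensions else False)
    return PoseScore(pose_id=pose_id, n_interface_residues=n_iface,
                     n_hbonds=len(hb), n_salt_bridges=len(sb),
                     in_groove=in_groove)


def rank_poses(poses: list[ComplexModel], cutoffs: Cutoffs | None = None,
               profile: PocketProfile | None = None,
               reference_index: int = 0,
               margin: float = GROOVE_MARGIN,
               include_ligand_residues: bool = False) -> list[PoseScore]:
    """Rank docking poses by the selection recipe.

    Poses out of the binding groove are discarded; the rest are sorted
    by H-bond + salt-bridge count (descending), then interface size
    (descending), then pose id (ascending). The reference pocket profile
    defaults to the one computed from ``poses[reference_index]``.
    """
    if not poses:
        return []
    cut = cutoffs or Cutoffs()
    if profile is None:
        if not (0 <= reference_index < len(poses)):
            raise ValueError("missing reference profile: bad reference index")
        profile = profile_pocket(poses[reference_index], iac_cutoff=cut.iac)
    scores = [score_pose(p, pose_id=i, cutoffs=cut, profile=profile,
                         margin=margin,
                         include_ligand_residues=include_ligand_residues)
              for i, p in enumerate(poses)]
    ranked = sorted((s for s in scores if s.in_groove),
                    key=lambda s: (-s.total, -s.n_interface_residues,
                                   s.pose_id))
    for rank, s in enumerate(ranked, start=1):
        s.rank = rank
    return ranked
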