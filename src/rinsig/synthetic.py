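"""Synthetic structure generation.

Everything the test surface needs is built here from internal
coordinates: ideal helices, short peptides in extended or turn
conformations (including N-formyl, acetyl/amide-capped, Aib and
D-residues), a seven-helix toy receptor with a cone-shaped pocket and
annotated anchor/activation/C-terminal residues, planted interaction
geometries, and stochastic trajectories with known statistics.

Side chains come from idealized rotamer templates — sufficient for
centroid, ring-plane and charged-group geometry; rotamer energetics are
irrelevant to the geometric detectors. D-residues are exact mirrors of
their L-parent across the N-CA-C plane; Aib carries two CB methyls.

All generators are fully deterministic under their seed.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .chem import get_template
from .geometry import place_atom, principal_axis
from .interactions import Cutoffs, detect_hbonds
from .structio import (Atom, ComplexModel, Residue, StructureModel,
                       assign_segments)
from .trajectory import Trajectory

#: default fixture seed, recorded in provenance
DEFAULT_SEED = 20190821

# backbone internal coordinates (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.46, 1.52, 1.33, 1.23
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.5

EXTENDED_PHI_PSI = (-120.0, 120.0)
HELIX_PHI_PSI = (-57.0, -47.0)
#: type-I beta-turn dihedrals for the two central turn residues
TURN_PHI_PSI = ((-60.0, -30.0), (-90.0, 0.0))

#: named peptide sequences used throughout the tests
SEQUENCES = {
    "fMLF": ["FME", "LEU", "PHE"],
    "SRSRY": ["SER", "ARG", "SER", "ARG", "TYR"],
    "RI3": ["ACE", "DTY", "DAR", "AIB", "DAR", "NH2"],
}

_D_RESIDUES = {"DAL", "DAR", "DSG", "DAS", "DCY", "DGN", "DGL", "DHI",
               "DIL", "DLE", "DLY", "DPN", "DPR", "DSN", "DTH", "DTR",
               "DTY", "DVA"}

# Side-chain build recipes: (atom, (ref_a, ref_b, ref_c), bond, angle,
# torsion). CB is placed first from the backbone improper; the rest
# chain off it with fixed idealized chi angles.
_CB = ("CB", ("N", "C", "CA"), 1.53, 110.5, 122.6)
_RING6 = [
    ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, 90.0),
    ("CD2", ("CA", "CB", "CG"), 1.39, 120.0, -90.0),
    ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
    ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
    ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
]
_SIDE_CHAINS: dict[str, list] = {
    "GLY": [],
    "ALA": [_CB],
    "AIB": [("CB1", ("N", "C", "CA"), 1.53, 110.5, 122.6),
            ("CB2", ("N", "C", "CA"), 1.53, 110.5, -122.6)],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.42, 111.0, -65.0)],
    "THR": [_CB, ("OG1", ("N", "CA", "CB"), 1.43, 109.5, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 111.0, 60.0)],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.81, 114.0, -65.0)],
    "VAL": [_CB, ("CG1", ("N", "CA", "CB"), 1.52, 111.0, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 111.0, 60.0)],
    "LEU": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.52, 111.0, 60.0),
            ("CD2", ("CA", "CB", "CG"), 1.52, 111.0, 180.0)],
    "ILE": [_CB, ("CG1", ("N", "CA", "CB"), 1.52, 111.0, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
            ("CD1", ("CA", "CB", "CG1"), 1.52, 114.0, 180.0)],
    "PRO": [_CB, ("CG", ("N", "CA", "CB"), 1.50, 104.0, -30.0),
            ("CD", ("CA", "CB", "CG"), 1.51, 105.0, 30.0)],
    "MET": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -65.0),
            ("SD", ("CA", "CB", "CG"), 1.80, 112.0, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.0, 180.0)],
    "PHE": [_CB, ("CG", ("N", "CA", "CB"), 1.50, 114.0, -65.0)] + _RING6,
    "TYR": [_CB, ("CG", ("N", "CA", "CB"), 1.50, 114.0, -65.0)] + _RING6
           + [("OH", ("CD1", "CE1", "CZ"), 1.36, 120.0, 180.0)],
    "TRP": [_CB, ("CG", ("N", "CA", "CB"), 1.50, 114.0, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.43, 127.0, -90.0),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.41, 107.0, 180.0),
            ("CE3", ("CG", "CD2", "CE2"), 1.40, 133.0, 180.0),
            ("CZ2", ("CD2", "CE2"), None, None, None),  # placed below
            ],
    "ASP": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 113.0, -65.0),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, 0.0),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, 180.0)],
    "ASN": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 113.0, -65.0),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.0, 0.0),
            ("ND2", ("CA", "CB", "CG"), 1.33, 118.0, 180.0)],
    "GLU": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 113.0, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.0, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.0, 180.0)],
    "GLN": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 113.0, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.0, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.33, 118.0, 180.0)],
    "LYS": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.0, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, 180.0)],
    "ARG": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.0, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
    "HIS": [_CB, ("CG", ("N", "CA", "CB"), 1.49, 114.0, -65.0),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.0, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.36, 129.0, -90.0),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 105.0, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0)],
}
# TRP second-ring completion (kept planar by 0/180 torsions)
_SIDE_CHAINS["TRP"] = [x for x in _SIDE_CHAINS["TRP"] if x[0] != "CZ2"] + [
    ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.0, 180.0),
    ("CZ3", ("CD2", "CE3"), None, None, None),
]
_SIDE_CHAINS["TRP"] = [x for x in _SIDE_CHAINS["TRP"] if x[0] != "CZ3"] + [
    ("CZ3", ("CE2", "CD2", "CE3"), 1.39, 118.0, 180.0),
    ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.0, 180.0),
]

_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S"}


def _element(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name[0], "C")


def _l_parent(name: str) -> str:
    if name in _D_RESIDUES:
        from .chem import _D_PARENT
        return _D_PARENT[name]
    return name


def parse_sequence(sequence) -> list[str]:
    """Sequence as a list of 3-letter codes, a dash-separated string, or
    one of the named presets ('fMLF', 'SRSRY', 'RI3')."""
    if isinstance(sequence, str):
        if sequence in SEQUENCES:
            return list(SEQUENCES[sequence])
        return [s.strip().upper() for s in sequence.split("-") if s.strip()]
    return [str(s).upper() for s in sequence]


def _mirror_side_chain(atoms: dict[str, np.ndarray]) -> None:
    """Reflect side-chain atoms across the N-CA-C plane (D-residue)."""
    n, ca, c = atoms["N"], atoms["CA"], atoms["C"]
    normal = np.cross(n - ca, c - ca)
    normal /= np.linalg.norm(normal)
    for name, pos in atoms.items():
        if name in ("N", "CA", "C", "O", "CN", "O1"):
            continue
        d = float(np.dot(pos - ca, normal))
        atoms[name] = pos - 2.0 * d * normal


def _build_chain(codes: list[str], phi_psi: list[tuple[float, float]],
                 chain_id: str, start_seq: int) -> list[Residue]:
    """Backbone + side chains for one chain from internal coordinates.

    ``phi_psi`` holds one (phi, psi) pair per amino-acid residue (caps
    excluded). Returns residues numbered from ``start_seq``.
    """
    aa_codes = [c for c in codes if c not in ("ACE", "NH2")]
    if len(phi_psi) != len(aa_codes):
        raise ValueError("need one (phi, psi) pair per amino-acid residue")
    for code in codes:
        get_template(code)   # fail early on unknown residue names
    pp = iter(phi_psi)
    residues: list[Residue] = []
    # virtual seed atoms so the first placement has a frame
    prev_ca = np.array([-2.0, 1.2, 0.0])
    prev_c = np.array([-1.33, 0.0, 0.0])
    next_n = np.array([0.0, 0.0, 0.0])
    seq = start_seq
    for code in codes:
        atoms: dict[str, np.ndarray] = {}
        if code == "ACE":
            # acetyl cap: CH3-C(=O)- ; CH3 plays the CA role in the chain
            ch3 = next_n          # reuse the seed position
            c = place_atom(prev_ca, prev_c, ch3, _B_CA_C, 111.0, 180.0)
            o = place_atom(prev_c, ch3, c, _B_C_O, _A_CA_C_O, 0.0)
            next_n = place_atom(prev_c, ch3, c, _B_C_N, _A_CA_C_N, 180.0)
            atoms = {"CH3": ch3, "C": c, "O": o}
            prev_ca, prev_c = ch3, c
        elif code == "NH2":
            atoms = {"N": next_n}
        else:
            phi, psi = next(pp)
            n = next_n
            ca = place_atom(prev_ca, prev_c, n, _B_N_CA, _A_C_N_CA, 180.0)
            c = place_atom(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi)
            next_n = place_atom(n, ca, c, _B_C_N, _A_CA_C_N, psi)
            o = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
            atoms = {"N": n, "CA": ca, "C": c, "O": o}
            parent = _l_parent(code)
            if code == "FME":
                # formyl group on the backbone nitrogen
                cn = place_atom(c, ca, n, 1.33, 120.0, 180.0)
                o1 = place_atom(ca, n, cn, _B_C_O, 120.5, 180.0)
                atoms["CN"], atoms["O1"] = cn, o1
                parent = "MET"
            for entry in _SIDE_CHAINS.get(parent if code != "AIB" else "AIB",
                                          []):
                name, refs, bond, ang, tor = entry
                a, b, cref = (atoms[r] for r in refs)
                atoms[name] = place_atom(a, b, cref, bond, ang, tor)
            if code in _D_RESIDUES:
                _mirror_side_chain(atoms)
            prev_ca, prev_c = ca, c
        residues.append(Residue(
            chain_id=chain_id, seq_num=seq, name=code,
            atoms=[Atom(serial=0, name=nm, element=_element(nm), coords=xyz)
                   for nm, xyz in atoms.items()]))
        # restore backbone flags (Atom default False)
        seq += 1
    _renumber(residues)
    _flag_backbone(residues)
    return residues


def _flag_backbone(residues: list[Residue]) -> None:
    from .structio import _is_backbone
    for res in residues:
        for a in res.atoms:
            a.is_backbone = _is_backbone(res.name, a.name)


def _renumber(residues: list[Residue], start: int = 1) -> None:
    serial = start
    for res in residues:
        for a in res.atoms:
            a.serial = serial
            serial += 1


def _renumber_model(model: StructureModel) -> None:
    serial = 1
    for res in model.residues():
        for a in res.atoms:
            a.serial = serial
            serial += 1


def build_helix(sequence, phi_deg: float = HELIX_PHI_PSI[0],
                psi_deg: float = HELIX_PHI_PSI[1], chain_id: str = "A",
                start_seq: int = 1) -> StructureModel:
    """Ideal alpha-helix (rise about 1.5 Å per residue)."""
    codes = parse_sequence(sequence)
    n_aa = sum(1 for c in codes if c not in ("ACE", "NH2"))
    residues = _build_chain(codes, [(phi_deg, psi_deg)] * n_aa,
                            chain_id, start_seq)
    return StructureModel(model_id=1, chains={chain_id: residues})


def _conformation_phi_psi(n_aa: int, conformation: str
                          ) -> list[tuple[float, float]]:
    if conformation == "extended":
        return [EXTENDED_PHI_PSI] * n_aa
    if conformation == "helix":
        return [HELIX_PHI_PSI] * n_aa
    if conformation == "turn":
        if n_aa < 4:
            raise ValueError("a turn needs at least 4 residues")
        pp = [EXTENDED_PHI_PSI] * n_aa
        pp[1], pp[2] = TURN_PHI_PSI
        # longer peptides: continue helically so CO(1)..NH(5) also closes
        for i in range(3, n_aa - 1):
            pp[i] = (-105.0, -15.0)
        return pp
    raise ValueError(f"unknown conformation {conformation!r}")


def build_peptide(sequence, conformation: str = "extended",
                  chain_id: str = "P", start_seq: int = 1
                  ) -> StructureModel:
    """Short peptide in an extended, helical or turn conformation.

    Extended uses (phi, psi) = (-120, +120); turn mode applies type-I
    beta-turn dihedrals at the two central residues, which closes the
    backbone CO(i)->NH(i+3) contact near 2.9 Å.
    """
    codes = parse_sequence(sequence)
    n_aa = sum(1 for c in codes if c not in ("ACE", "NH2"))
    residues = _build_chain(codes, _conformation_phi_psi(n_aa, conformation),
                            chain_id, start_seq)
    return StructureModel(model_id=1, chains={chain_id: residues})


# ---------------------------------------------------------------------------
# toy seven-helix receptor

#: residue numbering and special identities mirroring a formyl-peptide
#: receptor: anchor Phe81/Arg84/Lys85/Phe102, activation
#: Arg201/Arg205/Trp254/Tyr257, TM7 Asp284/Ser287/Phe291, C-terminal
#: serine triplet 328/332/338.
TOY_HELIX_RANGES = {
    "TM1": (40, 48), "TM2": (78, 86), "TM3": (100, 108), "TM4": (140, 148),
    "TM5": (198, 206), "TM6": (250, 258), "TM7": (284, 292),
}
TOY_CTERM_RANGE = (320, 340)
TOY_SPECIAL = {
    81: "PHE", 84: "ARG", 85: "LYS", 102: "PHE", 106: "ASP",
    201: "ARG", 205: "ARG", 254: "TRP", 257: "TYR",
    284: "ASP", 287: "SER", 291: "PHE",
    324: "LEU", 328: "SER", 330: "GLN", 332: "SER", 336: "THR",
    338: "SER", 340: "LEU",
}
TOY_SEGMENT_MAP = {seg: [rng] for seg, rng in TOY_HELIX_RANGES.items()}
TOY_SEGMENT_MAP["CTERM"] = [TOY_CTERM_RANGE]
TOY_ANCHOR = frozenset({81, 84, 85, 102})
TOY_ACTIVATION = frozenset({201, 205, 254, 257})


def _orient_helix(model: StructureModel, start: np.ndarray,
                  end: np.ndarray) -> StructureModel:
    """Rigidly move a helix so its axis runs start -> end (centered)."""
    coords = model.coords()
    axis = principal_axis(coords)
    ca = np.array([r.atom("CA").coords for r in model.residues()])
    # orient the axis along increasing residue index
    if float((ca[-1] - ca[0]) @ axis) < 0:
        axis = -axis
    target = end - start
    t_norm = target / np.linalg.norm(target)
    v = np.cross(axis, t_norm)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3) if float(axis @ t_norm) > 0 else \
            Rotation.from_rotvec(np.pi * _any_perp(axis)).as_matrix()
    else:
        angle = np.arccos(np.clip(float(axis @ t_norm), -1.0, 1.0))
        rot = Rotation.from_rotvec(angle * v / s).as_matrix()
    centered = coords - coords.mean(axis=0)
    new = centered @ rot.T + (start + end) / 2.0
    out = model.copy()
    out.set_coords(new)
    return out


def _any_perp(v: np.ndarray) -> np.ndarray:
    p = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(p) < 1e-8:
        p = np.cross(v, [1.0, 0.0, 0.0])
    return p / np.linalg.norm(p)


def build_toy_receptor(n_helices: int = 7, pocket_radius: float = 8.0,
                       pocket_depth: float = 13.0,
                       special_residues: dict[int, str] | None = None,
                       tip_radius: float = 3.0,
                       chain_id: str = "A") -> StructureModel:
    """Seven-helix toy receptor with a cone-shaped pocket.

    Helix axes sit on a circle and tilt inward so the pocket narrows
    from ``pocket_radius`` at the extracellular mouth (top, +z) to
    ``tip_radius`` at the membrane-side tip over a height of
    ``pocket_depth``. Pocket-lining positions carry the requested
    special residue identities; a C-terminal helix with the serine
    triplet hangs below the bundle. Segments are annotated TM1..TM7 and
    CTERM.
    """
    if n_helices < 1:
        raise ValueError("need at least one helix")
    special = dict(TOY_SPECIAL if special_residues is None else
                   special_residues)
    segs = list(TOY_HELIX_RANGES.items())[:n_helices]
    chains: list[Residue] = []
    # residue centroids spiral ~1.4 Å around the helix axis and spill
    # ~0.5 Å past its ends; compensate so the *measured* pocket matches
    # the requested dimensions
    spiral, overhang = 1.4, 0.45
    z_top = pocket_depth / 2.0 - overhang
    z_bot = -pocket_depth / 2.0 + overhang
    mouth_axis_r = max(pocket_radius - spiral, tip_radius)
    for k, (seg, (lo, hi)) in enumerate(segs):
        theta = 2.0 * np.pi * k / n_helices
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        start = tip_radius * u + np.array([0, 0, z_bot])
        end = mouth_axis_r * u + np.array([0, 0, z_top])
        codes = [special.get(num, "ALA") for num in range(lo, hi + 1)]
        helix = build_helix(codes, chain_id=chain_id, start_seq=lo)
        helix = _orient_helix(helix, start, end)
        chains.extend(helix.chains[chain_id])
    # C-terminal helix below the bundle, pointing down the z axis
    lo, hi = TOY_CTERM_RANGE
    codes = [special.get(num, "ALA") for num in range(lo, hi + 1)]
    cterm = build_helix(codes, chain_id=chain_id, start_seq=lo)
    length = 1.5 * (hi - lo)
    cterm = _orient_helix(cterm, np.array([0, 0, z_bot - 6.0]),
                          np.array([0, 0, z_bot - 6.0 - length]))
    chains.extend(cterm.chains[chain_id])
    model = StructureModel(model_id=1, chains={chain_id: chains})
    _renumber_model(model)
    segmap = {seg: [rng] for seg, rng in segs}
    segmap["CTERM"] = [TOY_CTERM_RANGE]
    return assign_segments(model, segmap)


# ---------------------------------------------------------------------------
# interaction planting


def _group_residues(model: StructureModel, keys) -> list[Residue]:
    return [model.residue(k) for k in keys]


def _hbond_partners(res_a: Residue, res_b: Residue):
    """(donor_res, donor_atom, antecedent_atom, acceptor_res,
    acceptor_atom), preferring donor on res_a and backbone atoms."""
    from .chem import get_template

    def donor_of(res):
        tpl = get_template(res.name)
        for name in ("N",) + tuple(sorted(tpl.donors)):
            if name in tpl.donors and res.atom(name) is not None:
                ante_name = tpl.donor_antecedent.get(name)
                ante = res.atom(ante_name) if ante_name else None
                if ante is not None:
                    return res.atom(name), ante
        return None, None

    def acceptor_of(res):
        tpl = get_template(res.name)
        for name in ("O", "O1") + tuple(sorted(tpl.acceptors)):
            if name in tpl.acceptors and res.atom(name) is not None:
                return res.atom(name)
        return None

    d, ante = donor_of(res_a)
    acc = acceptor_of(res_b)
    if d is not None and acc is not None:
        return res_a, d, ante, res_b, acc
    d, ante = donor_of(res_b)
    acc = acceptor_of(res_a)
    if d is not None and acc is not None:
        return res_b, d, ante, res_a, acc
    raise ValueError(
        f"no donor/acceptor pairing between {res_a.label} and {res_b.label}")


def _ring_centroid(res: Residue) -> np.ndarray:
    from .chem import get_template
    tpl = get_template(res.name)
    if not tpl.rings:
        raise ValueError(f"{res.label} has no aromatic ring")
    ring = tpl.rings[0]
    return np.array([res.atom(n).coords for n in sorted(ring)]).mean(axis=0)


def _translate_group(group: list[Residue], shift: np.ndarray) -> None:
    for res in group:
        for a in res.atoms:
            a.coords = a.coords + shift


def _rotate_group(group: list[Residue], center: np.ndarray,
                  rotmat: np.ndarray) -> None:
    for res in group:
        for a in res.atoms:
            a.coords = (a.coords - center) @ rotmat.T + center


def plant_interaction(model: StructureModel, kind: str,
                      pair: tuple, distance: float,
                      move_group: list[tuple] | None = None,
                      approach: np.ndarray | None = None
                      ) -> StructureModel:
    """Move residue(s) so a specific interaction exists at ``distance``.

    ``pair`` holds two residue keys (chain, seq, icode); the second
    residue — or the whole ``move_group`` containing it — is rigidly
    moved so the defining distance of ``kind`` equals ``distance``
    (within 0.05 Å). For H-bonds the moved side is also oriented so the
    donor-antecedent angle is well inside the geometric criterion.
    ``approach`` optionally fixes the direction (unit vector, from the
    fixed partner toward the moved one). The target distance must lie
    within the detector cutoff for ``kind``.
    """
    cut = Cutoffs()
    if kind not in ("hbond", "salt_bridge", "pi_cation", "pi_stacking",
                    "iac"):
        raise ValueError(f"unknown interaction kind {kind!r}")
    if not (0.0 < distance <= cut.for_kind(kind)):
        raise ValueError(
            f"target distance {distance} Å outside the {kind} cutoff "
            f"({cut.for_kind(kind)} Å)")
    out = model.copy()
    key_a, key_b = (tuple(k) if len(k) == 3 else (k[0], k[1], "")
                    for k in pair)
    res_a, res_b = out.residue(key_a), out.residue(key_b)
    group = _group_residues(out, move_group) if move_group else [res_b]
    if res_b not in group:
        raise ValueError("move_group must contain the second residue")

    from .chem import get_template

    if kind == "hbond":
        dres, datom, ante, ares, aatom = _hbond_partners(res_a, res_b)
        moved_holds_donor = dres is res_b
        w = datom.coords - ante.coords
        w = w / np.linalg.norm(w)
        if approach is not None:
            u = np.asarray(approach, float)
            u = u / np.linalg.norm(u)
        else:
            p = _any_perp(w)
            u = np.cos(np.radians(30.0)) * w + np.sin(np.radians(30.0)) * p
        if moved_holds_donor:
            # put the donor at distance from the fixed acceptor, then
            # orient the moved group so the antecedent angle is ~150 deg
            target_d = aatom.coords + distance * (u if approach is not None
                                                  else -u)
            _translate_group(group, target_d - datom.coords)
            v = ante.coords - datom.coords
            acc_dir = aatom.coords - datom.coords
            from .geometry import angle_deg
            cur = angle_deg(ante.coords, datom.coords, aatom.coords)
            axis = np.cross(v, acc_dir)
            if np.linalg.norm(axis) < 1e-9:
                axis = _any_perp(v)
            axis = axis / np.linalg.norm(axis)
            delta = np.radians(cur - 150.0)
            rot = Rotation.from_rotvec(delta * axis).as_matrix()
            _rotate_group(group, datom.coords, rot)
        else:
            target_acc = datom.coords + distance * u
            _translate_group(group, target_acc - aatom.coords)
    elif kind in ("salt_bridge", "iac"):
        if kind == "salt_bridge":
            tpl_a, tpl_b = get_template(res_a.name), get_template(res_b.name)
            if tpl_a.positive and tpl_b.negative:
                atoms_a = [res_a.atom(n) for n in sorted(tpl_a.positive)]
                atoms_b = [res_b.atom(n) for n in sorted(tpl_b.negative)]
            elif tpl_a.negative and tpl_b.positive:
                atoms_a = [res_a.atom(n) for n in sorted(tpl_a.negative)]
                atoms_b = [res_b.atom(n) for n in sorted(tpl_b.positive)]
            else:
                raise ValueError("residue pair carries no opposite charges")
            atoms_a = [a for a in atoms_a if a is not None]
            atoms_b = [a for a in atoms_b if a is not None]
        else:
            atoms_a, atoms_b = res_a.atoms, res_b.atoms
        pa, pb = min(((a, b) for a in atoms_a for b in atoms_b),
                     key=lambda ab: float(np.linalg.norm(
                         ab[0].coords - ab[1].coords)))
        d0 = pb.coords - pa.coords
        n0 = np.linalg.norm(d0)
        direction = (np.asarray(approach, float) if approach is not None
                     else (d0 / n0 if n0 > 1e-9 else np.array([0, 0, 1.0])))
        direction = direction / np.linalg.norm(direction)
        target = pa.coords + distance * direction
        _translate_group(group, target - pb.coords)
    else:  # pi_cation / pi_stacking
        if kind == "pi_cation":
            tpl_a = get_template(res_a.name)
            if tpl_a.positive:
                cat = next(res_a.atom(n) for n in sorted(tpl_a.positive)
                           if res_a.atom(n) is not None)
                ref_a, ref_b = cat.coords, _ring_centroid(res_b)
            else:
                ref_a = _ring_centroid(res_a)
                tpl_b = get_template(res_b.name)
                cat = next(res_b.atom(n) for n in sorted(tpl_b.positive)
                           if res_b.atom(n) is not None)
                ref_b = cat.coords
        else:
            ref_a, ref_b = _ring_centroid(res_a), _ring_centroid(res_b)
        d0 = ref_b - ref_a
        n0 = np.linalg.norm(d0)
        direction = (np.asarray(approach, float) if approach is not None
                     else (d0 / n0 if n0 > 1e-9 else np.array([0, 0, 1.0])))
        direction = direction / np.linalg.norm(direction)
        target = ref_a + distance * direction
        _translate_group(group, target - ref_b)
    return out


# ---------------------------------------------------------------------------
# trajectories


def make_trajectory(reference: StructureModel, mode: str = "gaussian",
                    sigma: float | np.ndarray = 0.1, n_frames: int = 100,
                    seed: int = DEFAULT_SEED, dt_ns: float = 1.0
                    ) -> Trajectory:
    """Stochastic trajectory around a reference structure.

    ``gaussian`` adds i.i.d. noise per coordinate with per-residue sigma
    (scalar or one value per residue, Å); ``rigid`` applies a random
    rotation and translation of the whole model per frame. Fully
    reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    ref = reference.coords()
    n_atoms = ref.shape[0]
    frames = np.empty((n_frames, n_atoms, 3))
    if mode == "gaussian":
        residues = list(reference.residues())
        sig = np.asarray(sigma, float)
        if sig.ndim == 0:
            per_atom = np.full(n_atoms, float(sig))
        else:
            if sig.shape != (len(residues),):
                raise ValueError("sigma must be scalar or one per residue")
            per_atom = np.concatenate([
                np.full(len(r.atoms), s) for r, s in zip(residues, sig)])
        for i in range(n_frames):
            frames[i] = ref + rng.normal(0.0, 1.0, ref.shape) \
                * per_atom[:, None]
    elif mode == "rigid":
        center = ref.mean(axis=0)
        for i in range(n_frames):
            rot = Rotation.random(random_state=rng).as_matrix()
            trans = rng.uniform(-20.0, 20.0, size=3)
            frames[i] = (ref - center) @ rot.T + center + trans
    else:
        raise ValueError(f"unknown trajectory mode {mode!r}")
    times = dt_ns * np.arange(n_frames, dtype=float)
    return Trajectory(topology=reference.copy(), frames=frames, times=times)


# ---------------------------------------------------------------------------
# shipped complex presets


def _key(chain: str, seq: int) -> tuple:
    return (chain, seq, "")


def _jitter(model: StructureModel, sigma: float, rng) -> None:
    if sigma > 0:
        coords = model.coords()
        model.set_coords(coords + rng.normal(0.0, sigma, coords.shape))


def _orient_for_polar_clearance(model: StructureModel, lig_keys: list,
                                ring_key: tuple) -> float:
    """Rigidly rotate the ligand about its planted ring centroid to the
    grid orientation maximizing the minimum distance between ligand
    donor/acceptor atoms and receptor acceptor/donor atoms.

    Rotations about the ring centroid preserve any centroid-anchored
    planted distance. The orientation grid is fixed, so the result is
    deterministic. Returns the achieved clearance margin (Å).
    """
    from scipy.spatial import cKDTree

    from .chem import get_template

    lig_set = set(lig_keys)
    rec_don, rec_acc = [], []
    for res in model.residues():
        if res.key in lig_set:
            continue
        tpl = get_template(res.name)
        for a in res.atoms:
            if a.name in tpl.donors:
                rec_don.append(a.coords)
            if a.name in tpl.acceptors:
                rec_acc.append(a.coords)
    tree_don = cKDTree(np.array(rec_don)) if rec_don else None
    tree_acc = cKDTree(np.array(rec_acc)) if rec_acc else None
    group = _group_residues(model, lig_keys)
    ring_res = model.residue(ring_key)
    centroid = _ring_centroid(ring_res)
    lig_atoms = [(r, a) for r in group for a in r.atoms]
    rel = np.array([a.coords for _, a in lig_atoms]) - centroid
    don_idx = [i for i, (r, a) in enumerate(lig_atoms)
               if a.name in get_template(r.name).donors]
    acc_idx = [i for i, (r, a) in enumerate(lig_atoms)
               if a.name in get_template(r.name).acceptors]

    def margin(points: np.ndarray) -> float:
        m = np.inf
        if don_idx and tree_acc is not None:
            m = min(m, float(tree_acc.query(points[don_idx])[0].min()))
        if acc_idx and tree_don is not None:
            m = min(m, float(tree_don.query(points[acc_idx])[0].min()))
        return m

    ref = ring_res.atom(sorted(get_template(ring_res.name).rings[0])[0])
    ref_dir = ref.coords - centroid
    ref_dir /= np.linalg.norm(ref_dir)
    best = (-np.inf, None)
    for az in range(0, 360, 30):
        for el in (-30, 0, 30, 60, 90):
            d = np.array([np.cos(np.radians(el)) * np.cos(np.radians(az)),
                          np.cos(np.radians(el)) * np.sin(np.radians(az)),
                          np.sin(np.radians(el))])
            r1, _ = Rotation.align_vectors(d[None, :], ref_dir[None, :])
            for roll in range(0, 360, 45):
                rm = (Rotation.from_rotvec(np.radians(roll) * d)
                      * r1).as_matrix()
                m = margin(rel @ rm.T + centroid)
                if m > best[0]:
                    best = (m, rm)
    _rotate_group(group, centroid, best[1])
    return best[0]


def agonist_complex(seed: int = DEFAULT_SEED, noise_sigma: float = 0.05
                    ) -> ComplexModel:
    """Agonist-bound preset: a formyl-peptide-like ligand H-bonded into
    the pocket with an MM chain running through TM7 to the C-terminal
    region (an existing activation signature).

    The ligand's first residue MM-H-bonds the TM7 serine; the TM7 helix
    carries the chain down via its own i -> i+4 backbone bonds; a
    planted bond links the TM7 end to the C-terminal helix. The ligand's
    last residue MM-H-bonds the anchor-region lysine (two-point
    binding).
    """
    rng = np.random.default_rng(seed)
    receptor = build_toy_receptor()
    ligand = build_peptide("fMLF", conformation="extended", chain_id="P")
    # drop the ligand into the pocket mouth
    lig_res = ligand.chains["P"]
    shift = np.array([0.0, 0.0, 10.0]) - ligand.coords().mean(axis=0)
    for r in lig_res:
        for a in r.atoms:
            a.coords = a.coords + shift
    model = StructureModel(
        model_id=1,
        chains={"A": receptor.copy().chains["A"], "P": lig_res})
    _renumber_model(model)
    lig_keys = [r.key for r in model.chains["P"]]
    # Ser287 backbone N donates to the ligand Met1 formyl O (MM);
    # approach from above the mouth
    model = plant_interaction(
        model, "hbond", (_key("A", 287), lig_keys[0]), 2.9,
        move_group=lig_keys)
    # anchor contact: ligand Phe3 backbone N donates to Lys85 O (MM)
    model = plant_interaction(
        model, "hbond", (_key("A", 85), lig_keys[2]), 2.9,
        move_group=[lig_keys[2]])
    # bridge the TM7 intracellular end to the C-terminal helix: the
    # first C-terminal residue's N donates to the O of TM7 residue 292
    cterm_keys = [r.key for r in model.chains["A"]
                  if r.segment == "CTERM"]
    model = plant_interaction(
        model, "hbond", (_key("A", 292), _key("A", 320)), 2.9,
        move_group=cterm_keys)
    _jitter(model, noise_sigma, rng)
    out = ComplexModel(structure=model, ligand_chain="P")
    return out


def pocket_probe_complex(pocket_radius: float = 8.0,
                         pocket_depth: float = 13.0,
                         probe_length: float = 10.0,
                         seed: int = DEFAULT_SEED,
                         noise_sigma: float = 0.0) -> ComplexModel:
    """Toy receptor with an extended poly-Ala probe peptide docked along
    the pocket axis — the fixture for recovering the requested cone
    dimensions from :func:`rinsig.pocket.profile_pocket`."""
    rng = np.random.default_rng(seed)
    receptor = build_toy_receptor(pocket_radius=pocket_radius,
                                  pocket_depth=pocket_depth)
    n_res = max(2, int(round(probe_length / 3.45)))
    probe = build_peptide(["ALA"] * n_res, conformation="extended",
                          chain_id="P")
    # align the probe backbone with the pocket axis, top at the mouth
    ca = np.array([r.atom("CA").coords for r in probe.residues()])
    axis = principal_axis(ca)
    if float((ca[-1] - ca[0]) @ axis) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, -1.0]]),
                                    axis[None, :])
    R = rot.as_matrix()
    center = probe.coords().mean(axis=0)
    span = (ca[-1] - ca[0]) @ axis
    z_top = pocket_depth / 2.0
    target = np.array([0.0, 0.0, z_top - span / 2.0])
    for r in probe.chains["P"]:
        for a in r.atoms:
            a.coords = (a.coords - center) @ R.T + target
    model = StructureModel(
        model_id=1,
        chains={"A": receptor.copy().chains["A"], "P": probe.chains["P"]})
    _renumber_model(model)
    _jitter(model, noise_sigma, rng)
    return ComplexModel(structure=model, ligand_chain="P")


def antagonist_complex(seed: int = DEFAULT_SEED, noise_sigma: float = 0.05
                       ) -> ComplexModel:
    """Antagonist-bound preset: a capped retro-inverso-like turn ligand
    capping the pocket mouth, engaging the anchor region only through a
    cation-π contact (rim lysine to the ligand's aromatic ring) — no
    H-bond into the receptor, hence no activation signature.
    """
    rng = np.random.default_rng(seed)
    receptor = build_toy_receptor()
    ligand = build_peptide("RI3", conformation="turn", chain_id="P")
    lig_res = ligand.chains["P"]
    # park the ligand above the mouth with the tyrosine ring facing down
    ring = _ring_centroid(next(r for r in lig_res if r.name == "DTY"))
    lig_centroid = ligand.coords().mean(axis=0)
    down = ring - lig_centroid
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, -1.0]]),
                                    down[None, :])
    R = rot.as_matrix()
    for r in lig_res:
        for a in r.atoms:
            a.coords = (a.coords - lig_centroid) @ R.T
    z_top = receptor.coords()[:, 2].max()
    shift = np.array([0.0, 0.0, z_top + 6.0])
    for r in lig_res:
        for a in r.atoms:
            a.coords = a.coords + shift
    model = StructureModel(
        model_id=1,
        chains={"A": receptor.copy().chains["A"], "P": lig_res})
    _renumber_model(model)
    lig_keys = [r.key for r in model.chains["P"]]
    dty_key = next(r.key for r in model.chains["P"] if r.name == "DTY")
    # engage the rim lysine of the anchor region from outside the
    # bundle: approach along the lysine's outward radial, tilted above
    # the rim, so the ligand flanks the mouth instead of entering the
    # crowded cone
    nz = model.residue(_key("A", 85)).atom("NZ").coords
    outward = nz.copy()
    outward[2] = 0.0
    outward /= np.linalg.norm(outward)
    tilt = np.radians(30.0)
    approach = np.cos(tilt) * outward + np.sin(tilt) * np.array([0., 0., 1.])
    model = plant_interaction(
        model, "pi_cation", (_key("A", 85), dty_key), 5.8,
        move_group=lig_keys, approach=approach)
    # any rigid rotation about the planted ring centroid preserves the
    # cation-pi distance; pick the one that keeps ligand donor/acceptor
    # atoms farthest from receptor acceptor/donor atoms so no
    # incidental H-bond can form
    _orient_for_polar_clearance(model, lig_keys, dty_key)
    _jitter(model, noise_sigma, rng)
    out = ComplexModel(structure=model, ligand_chain="P")
    # construction invariant: an antagonist fixture must not H-bond the
    # receptor at all
    lig = set(lig_keys)
    for e in detect_hbonds(out):
        if (e.key_a in lig) != (e.key_b in lig):
            raise RuntimeError(
                f"antagonist preset grew a ligand-receptor H-bond: {e!r}")
    return out
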