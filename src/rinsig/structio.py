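"""Structure I/O and annotation.

Lightweight domain types (:class:`Atom`, :class:`Residue`,
:class:`StructureModel`, :class:`ComplexModel`) plus PDB reading/writing
(delegated to gemmi) and receptor segment annotation (N-term, TM1-TM7,
loops, C-term).

Coordinates are Å throughout. Residue numbering and chain ids are
preserved verbatim from the file; no renumbering ever happens. Highest-
occupancy altloc conformers are kept; insertion codes are preserved.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .chem import element_mass, get_template, has_template

#: Valid receptor segment labels.
SEGMENTS = frozenset(
    {"NTERM", "CTERM", "LIGAND", "UNASSIGNED"}
    | {f"TM{i}" for i in range(1, 8)}
    | {f"ECL{i}" for i in range(1, 4)}
    | {f"ICL{i}" for i in range(1, 4)}
)

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
# backbone-equivalent cap/formyl atoms (see chem module)
_BACKBONE_EQUIV = {
    "ACE": {"C", "O", "CH3"},
    "NH2": {"N"},
    "FME": _BACKBONE_NAMES | {"CN", "O1"},
}


class PDBParseError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # 3-vector, Å
    mass: float = 0.0
    is_backbone: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")
        if self.mass <= 0.0:
            self.mass = element_mass(self.element)


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    name: str
    atoms: list[Atom]
    icode: str = ""
    segment: str = "UNASSIGNED"
    sse: str = "unassigned"   # helix | strand | loop | unassigned

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.name} {self.chain_id}{self.seq_num}: "
                "duplicate atom names")

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, seq_num, icode) — unique within a model."""
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_num}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


@dataclass
class StructureModel:
    model_id: int
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self):
        if not any(self.chains.values()):
            raise ValueError("model must contain at least one residue")
        seen = set()
        for res in self.residues():
            if res.key in seen:
                raise ValueError(f"duplicate residue key {res.key}")
            seen.add(res.key)

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def residue(self, key: tuple[str, int, str]) -> Residue:
        for res in self.chains.get(key[0], ()):
            if res.key == key:
                return res
        raise KeyError(key)

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self) -> np.ndarray:
        """All heavy-atom coordinates as an (n, 3) array, in model order."""
        return np.array([a.coords for a in self.atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms(), coords):
            atom.coords = xyz.copy()

    def copy(self) -> "StructureModel":
        chains = {
            cid: [replace(res, atoms=[replace(a, coords=a.coords.copy())
                                      for a in res.atoms])
                  for res in residues]
            for cid, residues in self.chains.items()
        }
        return StructureModel(model_id=self.model_id, chains=chains)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """A copy with every atom rigidly moved: x -> R x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out.set_coords(out.coords() @ R.T + t)
        return out


@dataclass
class ComplexModel:
    """A receptor-peptide complex: one ligand chain, the rest receptor."""
    structure: StructureModel
    ligand_chain: str
    receptor_chains: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.receptor_chains is None:
            self.receptor_chains = frozenset(
                c for c in self.structure.chains if c != self.ligand_chain)
        else:
            self.receptor_chains = frozenset(self.receptor_chains)
        if self.ligand_chain in self.receptor_chains:
            raise ValueError("ligand chain cannot also be a receptor chain")
        if not self.structure.chains.get(self.ligand_chain):
            raise ValueError(f"ligand chain {self.ligand_chain!r} is empty")
        for res in self.ligand_residues():
            res.segment = "LIGAND"

    def ligand_residues(self) -> list[Residue]:
        return list(self.structure.chains[self.ligand_chain])

    def receptor_residues(self) -> list[Residue]:
        return [r for c in sorted(self.receptor_chains)
                for r in self.structure.chains[c]]


def _is_backbone(res_name: str, atom_name: str) -> bool:
    extra = _BACKBONE_EQUIV.get(res_name.upper())
    if extra is not None:
        return atom_name in extra
    return atom_name in _BACKBONE_NAMES


def _convert_residue(chain_id: str, gres: gemmi.Residue) -> Residue:
    # keep the highest-occupancy altloc per atom name (first on ties)
    chosen: dict[str, gemmi.Atom] = {}
    for ga in gres:
        prev = chosen.get(ga.name)
        if prev is None or ga.occ > prev.occ:
            chosen[ga.name] = ga
    atoms = []
    for ga in gres:   # preserve file order
        if chosen.get(ga.name) is not ga:
            continue
        elem = ga.element.name if ga.element and ga.element.name else "C"
        atoms.append(Atom(
            serial=ga.serial, name=ga.name, element=elem,
            coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
            is_backbone=_is_backbone(gres.name, ga.name)))
    icode = gres.seqid.icode.strip()
    return Residue(chain_id=chain_id, seq_num=gres.seqid.num,
                   icode=icode, name=gres.name.strip(), atoms=atoms)


def read_pdb(path: str | os.PathLike, multi_model: bool = False
             ) -> list[StructureModel]:
    """Read a PDB file into one or more :class:`StructureModel`.

    With ``multi_model=False`` only the first MODEL is returned (still as
    a one-element list). HETATM peptide residues (FME, AIB, D-residues,
    caps) are retained as ordinary residues.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise PDBParseError(f"{path}: empty file")
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    models = []
    for i, gmodel in enumerate(st):
        chains: dict[str, list[Residue]] = {}
        for gchain in gmodel:
            lst = chains.setdefault(gchain.name, [])
            for gres in gchain:
                if not any(not a.is_hydrogen() for a in gres):
                    continue
                res = _convert_residue(gchain.name, gres)
                res.atoms = [a for a in res.atoms
                             if a.element.upper() not in ("H", "D")]
                if res.atoms:
                    lst.append(res)
        chains = {c: r for c, r in chains.items() if r}
        if not chains:
            raise PDBParseError(f"{path}: model {i + 1} has no heavy atoms")
        models.append(StructureModel(model_id=i + 1, chains=chains))
        if not multi_model:
            break
    if not models:
        raise PDBParseError(f"{path}: no models found")
    return models


def write_pdb(models: list[StructureModel] | StructureModel,
              path: str | os.PathLike) -> None:
    """Write one or more models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    if not models:
        raise ValueError("nothing to write")
    st = gemmi.Structure()
    st.name = "rinsig"
    for i, model in enumerate(models, start=1):
        gm = gemmi.Model(i)
        for chain_id, residues in model.chains.items():
            gc = gemmi.Chain(chain_id)
            for res in residues:
                gr = gemmi.Residue()
                gr.name = res.name
                gr.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
                gr.het_flag = "A" if gemmi.find_tabulated_residue(
                    res.name) and gemmi.find_tabulated_residue(
                    res.name).is_amino_acid() else "H"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.serial = atom.serial
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.coords)
                    ga.occ = 1.0
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(os.fspath(path))


# ---------------------------------------------------------------------------
# segment annotation


def _parse_range(spec) -> tuple[int, int]:
    if isinstance(spec, str):
        lo, _, hi = spec.partition("-")
        lo, hi = int(lo), int(hi)
    else:
        lo, hi = int(spec[0]), int(spec[1])
    if hi < lo:
        raise ConfigError(f"invalid residue range {spec!r}")
    return lo, hi


def normalize_segment_map(segment_map: dict) -> dict[str, list[tuple[int, int]]]:
    """Validate and normalize a segment map.

    Accepted input: ``{label: "start-end"}``, ``{label: [start, end]}`` or
    ``{label: ["a-b", "c-d", ...]}``. Labels must be valid segment names;
    ranges must not overlap.
    """
    norm: dict[str, list[tuple[int, int]]] = {}
    for label, spec in (segment_map or {}).items():
        lbl = str(label).upper()
        if lbl not in SEGMENTS:
            raise ConfigError(
                f"unknown segment label {label!r}; valid: {sorted(SEGMENTS)}")
        if isinstance(spec, (list, tuple)) and spec and \
                isinstance(spec[0], (list, tuple, str)):
            ranges = [_parse_range(s) for s in spec]
        else:
            ranges = [_parse_range(spec)]
        norm.setdefault(lbl, []).extend(ranges)
    flat = [(lo, hi, lbl) for lbl, rs in norm.items() for lo, hi in rs]
    flat.sort()
    for (lo1, hi1, l1), (lo2, hi2, l2) in zip(flat, flat[1:]):
        if lo2 <= hi1:
            raise ConfigError(
                f"overlapping segment ranges: {l1} {lo1}-{hi1} and "
                f"{l2} {lo2}-{hi2}")
    return norm


def assign_segments(model: StructureModel, segment_map: dict,
                    chains: set[str] | None = None) -> StructureModel:
    """Label residues with receptor segments from a residue-range map.

    Every residue in the targeted chains gets a label; residues outside
    all ranges become ``UNASSIGNED``. Returns a new model.
    """
    norm = normalize_segment_map(segment_map)
    out = model.copy()
    for res in out.residues():
        if chains is not None and res.chain_id not in chains:
            continue
        if res.segment == "LIGAND":
            continue
        label = "UNASSIGNED"
        for lbl, ranges in norm.items():
            if any(lo <= res.seq_num <= hi for lo, hi in ranges):
                label = lbl
                break
        res.segment = label
    return out


def check_templates(model: StructureModel) -> None:
    """Raise if any residue in the model lacks a chemical template."""
    missing = sorted({r.name for r in model.residues() if not has_template(r.name)})
    if missing:
        raise ConfigError(f"residues without chemical template: {missing}")


def residue_template(res: Residue):
    return get_template(res.name)
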