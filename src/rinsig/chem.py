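"""Chemical templates: per-residue donor/acceptor/charge/ring atom roles.

The registry covers the 20 standard amino acids plus the nonstandard
residues needed for formyl-peptide and retro-inverso peptide work:

* ``FME`` — N-formyl-methionine. The formyl oxygen (``O1``) is an
  acceptor; the formylated backbone nitrogen is treated as a non-donor.
  Formyl atoms count as backbone-equivalent, so H-bonds through the
  formyl group classify as main-chain (MM/MS).
* ``AIB`` — alpha-aminoisobutyric acid: two Calpha methyls, no functional
  side chain; backbone donor/acceptor only.
* D-amino acids (``DTY``, ``DAR``, ...) — share the chemistry of their
  L-parent: chirality does not change atom roles.
* Caps ``ACE`` (acetyl: carbonyl O acceptor) and ``NH2`` (amide cap:
  N donor); both backbone-equivalent so that capped-peptide backbone
  H-bonds are classifiable as MM.

All roles are defined on heavy atoms only; modeled and docked structures
typically carry no hydrogens, and the geometric interaction criteria
downstream are heavy-atom criteria.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChemTemplate:
    """Atom roles for one residue type."""
    name: str
    donors: frozenset[str]
    acceptors: frozenset[str]
    positive: frozenset[str]      # side-chain cationic group atoms
    negative: frozenset[str]      # side-chain anionic group atoms
    rings: tuple[frozenset[str], ...]  # aromatic ring atom sets (>= 5 atoms)
    backbone: frozenset[str]      # backbone or backbone-equivalent atoms
    donor_antecedent: dict[str, str] = field(default_factory=dict)
    chem_class: str = "hydrophobic"  # positive|negative|aromatic|polar|hydrophobic

    def is_backbone_atom(self, atom_name: str) -> bool:
        return atom_name in self.backbone


_BB = frozenset({"N", "CA", "C", "O", "OXT"})
_BB_DON = {"N": "CA"}


def _t(name, *, donors=(), acceptors=(), positive=(), negative=(), rings=(),
       backbone=_BB, antecedent=None, chem_class="hydrophobic",
       n_is_donor=True):
    don = dict(_BB_DON) if n_is_donor else {}
    if antecedent:
        don.update(antecedent)
    all_donors = frozenset(don) | frozenset(donors)
    for d in donors:
        don.setdefault(d, "CB")
    return ChemTemplate(
        name=name,
        donors=all_donors,
        acceptors=frozenset({"O", "OXT"}) | frozenset(acceptors),
        positive=frozenset(positive),
        negative=frozenset(negative),
        rings=tuple(frozenset(r) for r in rings),
        backbone=frozenset(backbone),
        donor_antecedent=don,
        chem_class=chem_class,
    )


_PHE_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
_TRP_RING = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
_HIS_RING = ("CG", "ND1", "CD2", "CE1", "NE2")

_REGISTRY: dict[str, ChemTemplate] = {}

for tpl in [
    _t("ALA"),
    _t("GLY"),
    _t("VAL"),
    _t("LEU"),
    _t("ILE"),
    _t("PRO", n_is_donor=False),   # imino nitrogen has no H
    _t("MET"),
    _t("CYS", chem_class="polar"),
    _t("SER", donors=("OG",), acceptors=("OG",),
       antecedent={"OG": "CB"}, chem_class="polar"),
    _t("THR", donors=("OG1",), acceptors=("OG1",),
       antecedent={"OG1": "CB"}, chem_class="polar"),
    _t("ASN", donors=("ND2",), acceptors=("OD1",),
       antecedent={"ND2": "CG"}, chem_class="polar"),
    _t("GLN", donors=("NE2",), acceptors=("OE1",),
       antecedent={"NE2": "CD"}, chem_class="polar"),
    _t("ASP", acceptors=("OD1", "OD2"), negative=("OD1", "OD2"),
       chem_class="negative"),
    _t("GLU", acceptors=("OE1", "OE2"), negative=("OE1", "OE2"),
       chem_class="negative"),
    _t("LYS", donors=("NZ",), positive=("NZ",),
       antecedent={"NZ": "CE"}, chem_class="positive"),
    _t("ARG", donors=("NE", "NH1", "NH2"), positive=("NE", "NH1", "NH2"),
       antecedent={"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
       chem_class="positive"),
    # histidine: aromatic ring, both ring nitrogens acceptors/donors;
    # charge handled by an explicit protonation switch in the detectors.
    _t("HIS", donors=("ND1", "NE2"), acceptors=("ND1", "NE2"),
       positive=("ND1", "NE2"), rings=(_HIS_RING,),
       antecedent={"ND1": "CG", "NE2": "CE1"}, chem_class="positive"),
    _t("PHE", rings=(_PHE_RING,), chem_class="aromatic"),
    _t("TYR", donors=("OH",), acceptors=("OH",), rings=(_PHE_RING,),
       antecedent={"OH": "CZ"}, chem_class="aromatic"),
    _t("TRP", donors=("NE1",), rings=(_TRP_RING,),
       antecedent={"NE1": "CD1"}, chem_class="aromatic"),
    # N-formyl-methionine: formyl O1 accepts; formylated N does not donate.
    _t("FME", acceptors=("O1",), backbone=_BB | {"CN", "O1"},
       n_is_donor=False),
    # alpha-aminoisobutyric acid: no side-chain function at all.
    _t("AIB"),
    # acetyl cap: carbonyl only, backbone-equivalent.
    ChemTemplate(name="ACE", donors=frozenset(), acceptors=frozenset({"O"}),
                 positive=frozenset(), negative=frozenset(), rings=(),
                 backbone=frozenset({"C", "O", "CH3"}),
                 donor_antecedent={}, chem_class="hydrophobic"),
    # amide cap: the nitrogen donates; its antecedent is the preceding
    # carbonyl carbon, resolved by covalent-neighbor search at detection.
    ChemTemplate(name="NH2", donors=frozenset({"N"}), acceptors=frozenset(),
                 positive=frozenset(), negative=frozenset(), rings=(),
                 backbone=frozenset({"N"}),
                 donor_antecedent={}, chem_class="polar"),
]:
    _REGISTRY[tpl.name] = tpl

# D-amino acids: identical atom roles to the L-parent.
_D_PARENT = {
    "DAL": "ALA", "DAR": "ARG", "DSG": "ASN", "DAS": "ASP", "DCY": "CYS",
    "DGN": "GLN", "DGL": "GLU", "DHI": "HIS", "DIL": "ILE", "DLE": "LEU",
    "DLY": "LYS", "MED": "MET", "DPN": "PHE", "DPR": "PRO", "DSN": "SER",
    "DTH": "THR", "DTR": "TRP", "DTY": "TYR", "DVA": "VAL",
}
for dname, parent in _D_PARENT.items():
    p = _REGISTRY[parent]
    _REGISTRY[dname] = ChemTemplate(
        name=dname, donors=p.donors, acceptors=p.acceptors,
        positive=p.positive, negative=p.negative, rings=p.rings,
        backbone=p.backbone, donor_antecedent=dict(p.donor_antecedent),
        chem_class=p.chem_class)


class UnknownResidueError(KeyError):
    pass


def get_template(residue_name: str) -> ChemTemplate:
    """Template for a 3-letter residue code (case-insensitive).

    Raises :class:`UnknownResidueError` listing the registered names when
    the residue is not in the registry.
    """
    key = residue_name.strip().upper()
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownResidueError(
            f"no chemical template for residue {residue_name!r}; "
            f"registered: {', '.join(sorted(_REGISTRY))}") from None


def has_template(residue_name: str) -> bool:
    return residue_name.strip().upper() in _REGISTRY


def registered_residues() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


# Atomic masses (Da) for the elements occurring in peptides; used for
# mass-weighted radius of gyration.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}


def element_mass(element: str) -> float:
    try:
        return ATOMIC_MASS[element.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown element {element!r}") from None
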