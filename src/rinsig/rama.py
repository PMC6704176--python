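"""Backbone dihedral angles and coarse Ramachandran classification.

Used for model quality control: the fraction of residues in allowed
regions of the Ramachandran plot is the standard single-number summary
for a comparative model. The regions here are coarse rectangular
approximations of the classic plot (generously allowed boxes around
the right-handed helix, sheet/extended and left-handed helix basins),
adequate for QC-level fractions but not a substitute for a
residue-level validation service.
"""
from __future__ import annotations

from dataclasses import dataclass

from .geometry import dihedral_deg
from .structio import Residue, StructureModel

#: (phi_min, phi_max, psi_min, psi_max) boxes; psi is wrapped to
#: (-180, 180]. Favored boxes sit inside the allowed ones.
_FAVORED = (
    (-160.0, -40.0, -80.0, 0.0),     # right-handed helix
    (-170.0, -50.0, 90.0, 180.0),    # sheet / extended
    (-170.0, -50.0, -180.0, -160.0),  # sheet, psi wrap-around
    (40.0, 80.0, 0.0, 80.0),         # left-handed helix
)
_ALLOWED = (
    (-180.0, -20.0, -120.0, 40.0),   # around the helical basin
    (-180.0, -20.0, 40.0, 180.0),    # around the extended basin
    (-180.0, -20.0, -180.0, -140.0),  # extended, psi wrap-around
    (20.0, 100.0, -40.0, 100.0),     # around the left-handed basin
)


@dataclass
class RamaEntry:
    residue: Residue
    phi: float | None   # degrees; None at chain termini / missing atoms
    psi: float | None
    region: str         # favored | allowed | outlier | undefined


def _in_boxes(phi: float, psi: float, boxes) -> bool:
    return any(p0 <= phi <= p1 and s0 <= psi <= s1
               for p0, p1, s0, s1 in boxes)


def classify_phi_psi(phi: float | None, psi: float | None) -> str:
    """Coarse region for one (phi, psi) pair in degrees."""
    if phi is None or psi is None:
        return "undefined"
    if _in_boxes(phi, psi, _FAVORED):
        return "favored"
    if _in_boxes(phi, psi, _ALLOWED):
        return "allowed"
    return "outlier"


def _bb(res: Residue, name: str):
    atom = res.atom(name)
    return None if atom is None else atom.coords


def backbone_dihedrals(model: StructureModel) -> list[RamaEntry]:
    """Phi/psi for every residue, chain by chain in file order.

    Chain termini (and residues missing backbone atoms, e.g. caps) get
    ``None`` angles and region ``undefined``.
    """
    out: list[RamaEntry] = []
    for residues in model.chains.values():
        for i, res in enumerate(residues):
            prev_c = _bb(residues[i - 1], "C") if i > 0 else None
            next_n = _bb(residues[i + 1], "N") \
                if i + 1 < len(residues) else None
            n, ca, c = _bb(res, "N"), _bb(res, "CA"), _bb(res, "C")
            phi = psi = None
            if all(x is not None for x in (n, ca, c)):
                if prev_c is not None:
                    phi = dihedral_deg(prev_c, n, ca, c)
                if next_n is not None:
                    psi = dihedral_deg(n, ca, c, next_n)
            out.append(RamaEntry(residue=res, phi=phi, psi=psi,
                                 region=classify_phi_psi(phi, psi)))
    return out


def region_fractions(model: StructureModel) -> dict[str, float]:
    """Fractions of classified residues per region, plus counts.

    Residues with undefined angles (termini, caps) are excluded from
    the denominator, matching the usual QC convention.
    """
    entries = [e for e in backbone_dihedrals(model)
               if e.region != "undefined"]
    n = len(entries)
    counts = {"favored": 0, "allowed": 0, "outlier": 0}
    for e in entries:
        counts[e.region] += 1
    out: dict[str, float] = {"n_classified": float(n)}
    for k, v in counts.items():
        out[k] = v / n if n else 0.0
    out["allowed_or_better"] = (
        (counts["favored"] + counts["allowed"]) / n if n else 0.0)
    return out
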