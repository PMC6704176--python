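"""Brute-force O(n²) reference implementations of every detector, and a
randomized small-fixture generator.

The oracles deliberately use plain nested loops and independent
geometry code so that agreement with the library's KD-tree detectors is
a meaningful check, not a tautology.
"""
from __future__ import annotations

import numpy as np

from rinsig.chem import get_template
from rinsig.geometry import random_rigid_transform
from rinsig.interactions import Cutoffs
from rinsig.structio import ComplexModel, StructureModel
from rinsig.synthetic import build_peptide

RESIDUE_POOL = ["ALA", "SER", "ARG", "ASP", "GLU", "LYS", "TYR", "PHE",
                "LEU", "THR", "ASN", "HIS", "TRP"]


def random_complex(rng: np.random.Generator, box: float = 18.0
                   ) -> ComplexModel:
    """Two randomly placed short chains (receptor A, ligand P) with
    chemically sensible per-residue geometry; <= 300 atoms."""
    def chain(chain_id, n_lo, n_hi):
        n = int(rng.integers(n_lo, n_hi + 1))
        seq = [RESIDUE_POOL[i] for i in rng.integers(0, len(RESIDUE_POOL),
                                                     size=n)]
        conf = ["extended", "helix", "turn"][int(rng.integers(0, 3))]
        if conf == "turn" and n < 4:
            conf = "extended"
        model = build_peptide(seq, conformation=conf, chain_id=chain_id)
        R, t = random_rigid_transform(rng)
        coords = model.coords()
        center = coords.mean(axis=0)
        shift = rng.uniform(-box / 2, box / 2, size=3)
        model.set_coords((coords - center) @ R.T + shift)
        return model.chains[chain_id]

    chains = {"A": chain("A", 4, 8), "P": chain("P", 2, 4)}
    st = StructureModel(model_id=1, chains=chains)
    return ComplexModel(structure=st, ligand_chain="P")


def _ang(a, b, c):
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _antecedent(res, donor_name, chain, idx):
    tpl = get_template(res.name)
    name = tpl.donor_antecedent.get(donor_name)
    if name is not None and res.atom(name) is not None:
        return res.atom(name).coords
    donor = res.atom(donor_name)
    best, best_d = None, 1.8
    for j in (idx - 1, idx, idx + 1):
        if 0 <= j < len(chain):
            for a in chain[j].atoms:
                if a is donor:
                    continue
                d = float(np.linalg.norm(a.coords - donor.coords))
                if d < best_d:
                    best, best_d = a.coords, d
    return best


def brute_hbonds(model, cut: Cutoffs | None = None):
    """Set of (donor key, acceptor key, donor atom, acceptor atom,
    hb_class) for every geometric H-bond pair (before the one-per-pair
    reduction), minus the MM sequence-neighbour exclusion."""
    cut = cut or Cutoffs()
    st = model.structure if isinstance(model, ComplexModel) else model
    out = {}
    for chain_d in st.chains.values():
        for di, dres in enumerate(chain_d):
            dtpl = get_template(dres.name)
            for datom in dres.atoms:
                if datom.name not in dtpl.donors:
                    continue
                ante = _antecedent(dres, datom.name, chain_d, di)
                if ante is None:
                    continue
                for ares in st.residues():
                    if ares.key == dres.key:
                        continue
                    atpl = get_template(ares.name)
                    for aatom in ares.atoms:
                        if aatom.name not in atpl.acceptors:
                            continue
                        d = float(np.linalg.norm(datom.coords
                                                 - aatom.coords))
                        if d > cut.hbond_distance or d < 1e-9:
                            continue
                        if _ang(ante, datom.coords,
                                aatom.coords) < cut.hbond_angle:
                            continue
                        cls = (("M" if datom.is_backbone else "S")
                               + ("M" if aatom.is_backbone else "S"))
                        if (cls == "MM" and dres.chain_id == ares.chain_id
                                and abs(dres.seq_num - ares.seq_num) <= 2):
                            continue
                        key = (dres.key, ares.key)
                        cand = (d, datom.serial, aatom.serial,
                                datom.name, aatom.name, cls)
                        if key not in out or cand[:3] < out[key][:3]:
                            out[key] = cand
    return {(k[0], k[1], v[3], v[4], v[5]) for k, v in out.items()}


def brute_salt_bridges(model, cut: Cutoffs | None = None):
    cut = cut or Cutoffs()
    st = model.structure if isinstance(model, ComplexModel) else model
    residues = list(st.residues())
    out = set()
    for pres in residues:
        ptpl = get_template(pres.name)
        if ptpl.name in ("HIS", "DHI") and not cut.protonate_his:
            pos = ()
        else:
            pos = [pres.atom(n) for n in ptpl.positive
                   if pres.atom(n) is not None]
        for nres in residues:
            if nres.key == pres.key:
                continue
            ntpl = get_template(nres.name)
            neg = [nres.atom(n) for n in ntpl.negative
                   if nres.atom(n) is not None]
            if any(float(np.linalg.norm(p.coords - n.coords))
                   <= cut.salt_bridge for p in pos for n in neg):
                out.add((pres.key, nres.key))
    return out


def _ring_centroids(st):
    out = []
    for res in st.residues():
        tpl = get_template(res.name)
        for ring in tpl.rings:
            atoms = [res.atom(n) for n in sorted(ring)]
            if any(a is None for a in atoms):
                continue
            out.append((res, np.array([a.coords for a in atoms])
                        .mean(axis=0)))
    return out


def brute_pi_cation(model, cut: Cutoffs | None = None):
    cut = cut or Cutoffs()
    st = model.structure if isinstance(model, ComplexModel) else model
    rings = _ring_centroids(st)
    out = set()
    for cres in st.residues():
        tpl = get_template(cres.name)
        if tpl.name in ("HIS", "DHI") and not cut.protonate_his:
            continue
        cats = [cres.atom(n) for n in tpl.positive
                if cres.atom(n) is not None]
        for rres, centroid in rings:
            if rres.key == cres.key:
                continue
            if any(float(np.linalg.norm(c.coords - centroid))
                   <= cut.pi_cation for c in cats):
                out.add((cres.key, rres.key))
    return out


def brute_pi_stacking(model, cut: Cutoffs | None = None):
    cut = cut or Cutoffs()
    st = model.structure if isinstance(model, ComplexModel) else model
    rings = _ring_centroids(st)
    out = set()
    for i, (r1, c1) in enumerate(rings):
        for r2, c2 in rings[i + 1:]:
            if r1.key == r2.key:
                continue
            if float(np.linalg.norm(c1 - c2)) <= cut.pi_stacking:
                a, b = sorted((r1.key, r2.key))
                out.add((a, b))
    return out


def brute_iac(cm: ComplexModel, cut: Cutoffs | None = None):
    cut = cut or Cutoffs()
    out = set()
    for lres in cm.ligand_residues():
        for rres in cm.receptor_residues():
            dmin = min(float(np.linalg.norm(la.coords - ra.coords))
                       for la in lres.atoms for ra in rres.atoms)
            if dmin <= cut.iac:
                out.add((lres.key, rres.key))
    return out
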