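# rinsig

Residue interaction networks and activation signatures for
receptor–peptide complexes.

## Scientific problem

Seven-transmembrane (GPCR-class) receptors such as the formyl peptide
receptor bind short peptide ligands in a cone-shaped pocket between the
helices. Structurally, agonists and antagonists can occupy overlapping
parts of that pocket, so the interesting question is not *whether* a
peptide binds but *what it does once bound*:

- **Agonists** (e.g. formyl tripeptides, or the uPAR-derived pentapeptide
  SRSRY) reach deep into the pocket, engage an **activation region** of
  the lining, and nucleate a chain of main-chain–main-chain (MM)
  hydrogen bonds that runs through the TM7 helix into the receptor's
  C-terminal region — the **activation signature** associated with
  signaling.
- **Antagonists** (e.g. retro-inverso tetrapeptides built from
  D-amino acids) sit at the pocket rim, engage only an **anchor region**
  (largely through aromatic/cationic contacts), cap the pocket mouth,
  and never form the MM H-bond chain.

`rinsig` operationalizes this analysis: geometric interaction detectors
(H-bonds with MM/MS/SM/SS classification, salt bridges, cation-π,
π-stacking, closest-atom contacts), a residue interaction network (RIN)
with a deterministic trace of the activation signature, pocket-geometry
profiling with a single-occupancy check, docking-pose ranking, and
trajectory descriptors (RMSD, RMSF, radius of gyration, H-bond
time series, turn/extended conformation calls). A `synthetic` module
builds reproducible fixtures — ideal helices, turn/extended peptides
(including N-formyl, Aib, D-residues and terminal caps), a seven-helix
toy receptor, and agonist/antagonist complex presets — so the whole
pipeline is testable without external data.

All criteria are heavy-atom criteria: modeled and docked structures
typically carry no hydrogens.

## Worked example

Classify a ligand as agonist-like or antagonist-like from a PDB file of
the complex (receptor chain A, peptide chain P):

```python
from rinsig import (read_pdb, assign_segments, check_templates,
                    ComplexModel, build_rin, trace_signature,
                    classify_contact_regions, TOY_SEGMENT_MAP)

model = read_pdb("complex.pdb")[0]
check_templates(model)                       # every residue has chemistry
model = assign_segments(model, TOY_SEGMENT_MAP)   # or your own TM map
cm = ComplexModel(structure=model, ligand_chain="P")

net = build_rin(cm)                          # all five interaction kinds
sig = trace_signature(net)                   # MM H-bond chain to CTERM
regions = classify_contact_regions(net)

print("activation signature:", sig.exists)
if sig.exists:
    print(" path:", " -> ".join(f"{r.name}{r.seq_num}" for r in sig.path))
    print(" segments crossed:", sorted(sig.segments_crossed))
print("anchor engaged:", regions.anchor_engaged,
      "| activation engaged:", regions.activation_engaged)
```

Try it end to end on the shipped synthetic presets:

```python
from rinsig import agonist_complex, antagonist_complex

for name, cm in [("agonist", agonist_complex(seed=1)),
                 ("antagonist", antagonist_complex(seed=1))]:
    sig = trace_signature(build_rin(cm))
    print(name, "->", "signature" if sig.exists else "no signature")
# agonist -> signature
# antagonist -> no signature
```

The same pipeline is scriptable from the shell:

```sh
rinsig synth fixture --kind complex --preset agonist --seed 1 --out ag.pdb
rinsig signature --complex ag.pdb            # JSON report to stdout
rinsig interactions --complex ag.pdb --kinds hbond,salt_bridge
rinsig pocket --complex ag.pdb
rinsig pose rank --poses poses.pdb           # multi-model PDB
rinsig traj summarize --traj traj.pdb
```

Exit codes: 0 success, 1 usage error, 2 data error. The resolved
configuration of every run is logged to stderr for provenance.

## Pocket geometry and pose ranking

```python
from rinsig import (pocket_probe_complex, profile_pocket,
                    check_single_occupancy, peptide_extent, rank_poses)

probe = pocket_probe_complex()
prof = profile_pocket(probe)            # depth/mouth radius from lining
print(f"depth {prof.depth:.1f} Å, mouth {prof.mouth_radius:.1f} Å")
# a cone of these dimensions cannot host two bound peptides at once:
print(check_single_occupancy(prof, 14.8))   # True
```

`rank_poses` reproduces a standard docking post-processing rule:
discard poses whose ligand centroid leaves the binding groove, then
rank by the number of receptor–ligand H-bonds plus salt bridges,
breaking ties by interface size. Ranking is fully deterministic.

## Reproducibility

Every stochastic generator takes an explicit integer seed; identical
seeds give byte-identical PDB outputs. Detectors and descriptors are
deterministic and invariant under rigid motion. `python
scripts/acceptance.py --seed 1 --out report.json` recomputes the
headline quantities.

See `docs/methods.md` for the exact geometric criteria and conventions.
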