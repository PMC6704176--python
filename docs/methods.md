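# Methods

All structural criteria operate on heavy atoms only; modeled and docked
structures typically carry no hydrogens. Distances are in ångströms,
angles in degrees. Every detector is deterministic and invariant under
rigid motion of the whole complex.

## Chemical templates (`rinsig.chem`)

Per-residue atom roles (H-bond donors with their covalent antecedents,
acceptors, cationic/anionic groups, aromatic rings, backbone membership,
coarse chemical class) are tabulated for the 20 standard amino acids
plus:

- `FME` (N-formyl-methionine): the formyl carbonyl oxygen `O1` is an
  acceptor; the formylated backbone nitrogen is treated as a non-donor
  (conservative, since no hydrogen positions are available to orient
  the single remaining N–H). Formyl atoms are backbone-equivalent.
- `AIB` (α-aminoisobutyric acid): backbone roles only.
- D-amino acids (`DTY`, `DAR`, …): identical roles to the L-parent;
  chirality does not change chemistry.
- Caps `ACE` (acetyl; carbonyl acceptor) and `NH2` (amide; donor), both
  backbone-equivalent so capped-peptide backbone H-bonds classify as MM.

Histidine ring nitrogens count as cationic only when the
`protonate_his` cutoff switch is enabled.

## Interaction detectors (`rinsig.interactions`)

All cutoffs live in one frozen `Cutoffs` dataclass (defaults below) and
can be overridden per call or via YAML on the CLI.

| Interaction | Criterion | Default cutoff |
|---|---|---|
| Hydrogen bond | donor–acceptor distance ≤ cutoff **and** angle(antecedent, donor, acceptor) ≥ 90° | 3.5 |
| Salt bridge | min distance between side-chain cationic and anionic group atoms | 4.0 |
| Cation-π | cationic atom to aromatic ring centroid | 6.0 |
| π-stacking | ring centroid to ring centroid (inter-plane angle recorded, not filtered) | 7.0 |
| IAC (closest-atom contact) | minimum heavy-atom distance, receptor–ligand pairs only | 8.0 |

H-bonds are classified MM/MS/SM/SS by the backbone membership of the
donor and acceptor atoms (donor side first). MM bonds between residues
with |Δseq| ≤ 2 on the same chain are excluded as trivially local. At
most one edge is kept per residue pair and kind — ordered
(donor → acceptor) pairs for H-bonds, unordered pairs for the symmetric
kinds — choosing the shortest-distance candidate, ties broken by atom
serial.

## Residue interaction network and activation signature (`rinsig.rin`)

The RIN has one node per residue (annotated with its segment: TM1–TM7,
loops, CTERM, LIGAND) and one edge per detected interaction. The
**activation signature** is traced by deterministic multi-source
breadth-first search over the MM H-bond subgraph (mode `strict_MM`;
`relaxed_MS` also admits MS/SM edges) from all ligand residues to any
CTERM residue, optionally required to pass through a given segment
(default TM7; implemented by node splitting). Neighbor expansion is
over sorted residue keys, so the reported path is unique and
reproducible.

`classify_contact_regions` reports whether the ligand engages the
anchor region (default residues 81, 84, 85, 102) and the activation
region (201, 205, 254, 257) through directional interactions (H-bond,
salt bridge, cation-π, π-stacking); IAC proximity alone never counts as
engagement, though the contacts are listed.

## Pocket geometry and poses (`rinsig.pocket`)

The pocket lining is the set of receptor residues with an IAC contact
to the ligand (or an explicit residue list). Dimensions are measured on
lining-residue centroids along their principal axis, oriented
tip → mouth (the mouth is the end nearer the ligand centroid): depth is
the extent along the axis, mouth radius the mean radial distance of the
mouth-end centroids. These are qualitative, procedure-dependent
surrogates and are treated as consistency checks, not precision
measurements. `check_single_occupancy` applies the cone-geometry
argument: a pocket of depth *d* and mouth radius *r* can hold only one
peptide of maximal extent *L* when *L* > *d* and *L* > *r* (strict) —
the peptide spans the whole cone, leaving no room for a second copy.

`rank_poses` filters out poses whose ligand centroid leaves the binding
groove (cylinder around the pocket axis), then sorts by receptor–ligand
H-bond + salt-bridge count, then interface size (residues within the
IAC cutoff), then pose id.

## Trajectory descriptors (`rinsig.trajectory`)

RMSD uses Kabsch superposition (scipy `Rotation.align_vectors`);
RMSF is the per-residue root-mean-square deviation from the mean
structure (for isotropic Gaussian jitter of width σ the expectation is
√3·σ); radius of gyration is mass-weighted by default. H-bond time
series evaluate the detector per frame at requested times.
Conformation calls follow the turn definition: a peptide is a **turn**
if an intrapeptide CO(i)→NH(i+3) or CO(i)→NH(i+4) MM H-bond is present,
**extended** otherwise (helix if the i→i+4 ladder dominates). Reports
carry both nm and Å (1 nm = 10 Å).

## Ramachandran QC (`rinsig.rama`)

φ/ψ are computed per chain; termini and caps are `undefined` and
excluded from the denominator. Classification uses coarse rectangular
boxes around the right-handed helical, extended/sheet and left-handed
basins (favored inside allowed). This is a QC-level summary, not a
substitute for a residue-level validation service.

## Synthetic fixtures (`rinsig.synthetic`)

Peptides and helices are built from internal coordinates (NeRF atom
placement) with standard bond lengths/angles; conformations: extended
(−120, +120), helix (−57, −47), turn (type-I β-turn dihedrals at the
two central residues, closing CO(1)→NH(4), with helical continuation so
longer peptides also close CO(1)→NH(5)). D-residues mirror the side
chain across the backbone plane. The toy receptor is a seven-helix
bundle around a cone-shaped pocket with an anchor region at the rim, an
activation region at depth, and a C-terminal segment positioned to
carry the MM relay. `plant_interaction` rigidly moves a ligand so a
chosen interaction holds at an exact distance; the agonist preset
plants pocket H-bonds that complete the signature relay, while the
antagonist preset caps the mouth with a rim-lysine cation-π contact and
verifies at construction time that no ligand–receptor H-bond exists.
Gaussian and rigid-body trajectory generators take explicit seeds;
identical seeds give identical frames. Preset parameters are fixed
study conditions, not tunables.
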