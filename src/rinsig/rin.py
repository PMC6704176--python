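"""Residue interaction networks and the activation signature.

A residue interaction network (RIN) takes the residues of a
receptor-peptide complex as nodes and the detected interactions
(H-bonds, salt bridges, π-cation, π-stacking, proximity contacts) as
edges. On top of the RIN this module implements:

* the **activation signature** — a chain of main-chain (MM) H-bonds
  leading from the bound peptide through the receptor (crossing TM7 in
  the agonist case) to the C-terminal region. Agonist-bound complexes
  show such a path; antagonist-bound complexes, which engage only the
  anchor sub-site by aromatic/ionic contacts, do not.
* classification of ligand contacts into **anchor** vs **activation**
  sub-sites of the binding pocket;
* comparison of two networks (shared / unique receptor-ligand edges).
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .interactions import Cutoffs, InteractionEdge, detect
from .structio import ComplexModel, Residue

#: Anchor sub-site shipped default: pocket residues that grip the ligand
#: without triggering signaling (FPR1 numbering).
DEFAULT_ANCHOR = frozenset({81, 84, 85, 102})
#: Activation sub-site shipped default: residues whose engagement starts
#: the signaling-relevant H-bond chain (FPR1 numbering).
DEFAULT_ACTIVATION = frozenset({201, 205, 254, 257})

#: Edge kinds that count as directed engagement; proximity (iac) alone
#: never sets an engagement flag.
ENGAGEMENT_KINDS = frozenset({"hbond", "salt_bridge", "pi_cation",
                              "pi_stacking"})


@dataclass
class ResidueInteractionNetwork:
    nodes: list[Residue]
    edges: list[InteractionEdge]
    ligand_chain: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = {r.key for r in self.nodes}
        for e in self.edges:
            if e.key_a not in keys or e.key_b not in keys:
                raise ValueError(f"edge endpoint not a node: {e!r}")
            if e.key_a == e.key_b:
                raise ValueError("self-loop")

    def node(self, key) -> Residue:
        for r in self.nodes:
            if r.key == key:
                return r
        raise KeyError(key)

    def ligand_keys(self) -> list[tuple]:
        return [r.key for r in self.nodes if r.chain_id == self.ligand_chain]

    def receptor_ligand_edges(self) -> list[InteractionEdge]:
        lig = set(self.ligand_keys())
        return [e for e in self.edges
                if (e.key_a in lig) != (e.key_b in lig)]

    def to_graph(self, kinds=None, hb_classes=None) -> nx.Graph:
        """Undirected graph view, optionally restricted by edge kind
        and (for H-bonds) by MM/MS/SM/SS class."""
        g = nx.Graph()
        for r in self.nodes:
            g.add_node(r.key, name=r.name, segment=r.segment,
                       chain=r.chain_id)
        for e in self.edges:
            if kinds is not None and e.kind not in kinds:
                continue
            if hb_classes is not None and e.kind == "hbond" \
                    and e.hb_class not in hb_classes:
                continue
            g.add_edge(e.key_a, e.key_b)
        return g


def build_rin(complex_model: ComplexModel,
              kinds=("hbond", "salt_bridge", "pi_cation", "pi_stacking",
                     "iac"),
              cutoffs: Cutoffs | None = None) -> ResidueInteractionNetwork:
    """Union of the requested detectors over the complex.

    Node and edge ordering is deterministic (chain, seq_num; then kind).
    """
    cut = cutoffs or Cutoffs()
    from .interactions import EDGE_KINDS
    for k in kinds:
        if k not in EDGE_KINDS:
            raise ValueError(f"unknown interaction kind {k!r}")
    edges: list[InteractionEdge] = []
    for kind in EDGE_KINDS:   # fixed order regardless of input order
        if kind in kinds:
            edges.extend(detect(kind, complex_model, cutoffs=cut))
    nodes = sorted(complex_model.structure.residues(), key=lambda r: r.key)
    edges.sort(key=lambda e: (e.kind, e.key_a, e.key_b))
    return ResidueInteractionNetwork(
        nodes=nodes, edges=edges, ligand_chain=complex_model.ligand_chain,
        provenance={"kinds": sorted(kinds), "cutoffs": cut.to_dict()})


@dataclass
class ActivationSignature:
    """An ordered MM H-bond path from the ligand to the C-terminal region."""
    exists: bool
    path: list[Residue] = field(default_factory=list)
    path_edges: list[InteractionEdge] = field(default_factory=list)
    entry_residue: Residue | None = None
    terminus: Residue | None = None
    segments_crossed: list[str] = field(default_factory=list)
    mode: str = "strict_MM"

    def to_dict(self) -> dict:
        return {
            "exists": self.exists,
            "mode": self.mode,
            "path": [r.label for r in self.path],
            "entry_residue": self.entry_residue.label
            if self.entry_residue else None,
            "terminus": self.terminus.label if self.terminus else None,
            "segments_crossed": self.segments_crossed,
        }


def _bfs(graph: nx.Graph, sources) -> tuple[dict, dict]:
    """Deterministic multi-source BFS: distances and predecessors.

    Neighbours are expanded in sorted key order so the produced paths
    are unique under the documented lowest-residue tie-break.
    """
    dist = {s: 0 for s in sources}
    pred = {s: None for s in sources}
    queue = deque(sorted(sources))
    while queue:
        u = queue.popleft()
        for v in sorted(graph.neighbors(u)):
            if v not in dist:
                dist[v] = dist[u] + 1
                pred[v] = u
                queue.append(v)
    return dist, pred


def _walk_back(pred: dict, node) -> list:
    path = [node]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    return path[::-1]


def trace_signature(rin: ResidueInteractionNetwork,
                    require_segment: str | None = "TM7",
                    mode: str = "strict_MM") -> ActivationSignature:
    """Shortest MM H-bond path from any ligand residue to the C-terminal
    region.

    ``mode='strict_MM'`` uses only MM-class H-bonds; ``mode='relaxed_MS'``
    additionally admits MS/SM links (the weaker-agonist case). When
    ``require_segment`` is set, only paths containing at least one node
    of that segment are accepted. Returns ``exists=False`` with an empty
    path when no such path is present.
    """
    if mode not in ("strict_MM", "relaxed_MS"):
        raise ValueError(f"unknown signature mode {mode!r}")
    classes = {"MM"} if mode == "strict_MM" else {"MM", "MS", "SM"}
    lig = rin.ligand_keys()
    cterm = [r.key for r in rin.nodes if r.segment == "CTERM"]
    if not lig:
        raise ValueError("network has no ligand residues")
    if not cterm:
        raise ValueError("no CTERM-annotated residues in the network")
    graph = rin.to_graph(kinds={"hbond"}, hb_classes=classes)
    edge_lookup = {}
    for e in rin.edges:
        if e.kind == "hbond" and e.hb_class in classes:
            edge_lookup.setdefault(frozenset((e.key_a, e.key_b)), e)

    dist_l, pred_l = _bfs(graph, lig)
    reachable = [c for c in cterm if c in dist_l]
    no_sig = ActivationSignature(exists=False, mode=mode)
    if not reachable:
        return no_sig
    # direct shortest path (tie-break: smallest distance, lowest key)
    target = min(reachable, key=lambda c: (dist_l[c], c))
    path_keys = _walk_back(pred_l, target)
    seg_ok = (require_segment is None or
              any(rin.node(k).segment == require_segment for k in path_keys))
    if not seg_ok:
        # shortest path constrained through the required segment
        dist_c, pred_c = _bfs(graph, cterm)
        via = [k for k in graph.nodes
               if rin.node(k).segment == require_segment
               and k in dist_l and k in dist_c]
        if not via:
            return no_sig
        s = min(via, key=lambda k: (dist_l[k] + dist_c[k], k))
        path_keys = _walk_back(pred_l, s) + _walk_back(pred_c, s)[::-1][1:]
        # drop any accidental revisits while keeping order
        seen, simple = set(), []
        for k in path_keys:
            if k in seen:
                while simple and simple[-1] != k:
                    seen.discard(simple.pop())
            else:
                seen.add(k)
                simple.append(k)
        path_keys = simple
    path = [rin.node(k) for k in path_keys]
    path_edges = [edge_lookup[frozenset((a, b))]
                  for a, b in zip(path_keys, path_keys[1:])]
    segments = []
    for r in path:
        if not segments or segments[-1] != r.segment:
            segments.append(r.segment)
    return ActivationSignature(
        exists=True, path=path, path_edges=path_edges,
        entry_residue=path[0], terminus=path[-1],
        segments_crossed=segments, mode=mode)


@dataclass
class RegionContactReport:
    """Per-ligand-residue partition of contacted receptor residues."""
    anchor_contacts: dict[tuple, list[tuple]]
    activation_contacts: dict[tuple, list[tuple]]
    other_contacts: dict[tuple, list[tuple]]
    anchor_engaged: bool
    activation_engaged: bool

    def to_dict(self) -> dict:
        fmt = lambda d: {f"{k[0]}:{k[1]}{k[2]}":
                         [f"{v[0]}:{v[1]}{v[2]}" for v in vals]
                         for k, vals in d.items()}
        return {
            "anchor_contacts": fmt(self.anchor_contacts),
            "activation_contacts": fmt(self.activation_contacts),
            "other_contacts": fmt(self.other_contacts),
            "anchor_engaged": self.anchor_engaged,
            "activation_engaged": self.activation_engaged,
        }


def _as_seq_set(residue_ids) -> set:
    """Residue-id sets may be plain seq numbers or (chain, seq) tuples."""
    return {r if isinstance(r, tuple) else int(r) for r in residue_ids}


def _matches(res: Residue, idset: set) -> bool:
    return res.seq_num in idset or (res.chain_id, res.seq_num) in idset


def classify_contact_regions(rin: ResidueInteractionNetwork,
                             anchor_set=DEFAULT_ANCHOR,
                             activation_set=DEFAULT_ACTIVATION
                             ) -> RegionContactReport:
    """Partition each ligand residue's receptor contacts into anchor,
    activation and other sets; engagement flags require a directional
    interaction (H-bond, salt bridge or π edge), never mere proximity.
    """
    a_set = _as_seq_set(anchor_set)
    v_set = _as_seq_set(activation_set)
    if a_set & v_set:
        raise ValueError("anchor and activation sets overlap")
    lig = set(rin.ligand_keys())
    anchor: dict[tuple, list] = {k: [] for k in sorted(lig)}
    activation: dict[tuple, list] = {k: [] for k in sorted(lig)}
    other: dict[tuple, list] = {k: [] for k in sorted(lig)}
    anchor_engaged = activation_engaged = False
    for e in rin.edges:
        in_a, in_b = e.key_a in lig, e.key_b in lig
        if in_a == in_b:
            continue
        lig_key, rec_res = (e.key_a, e.res_b) if in_a else (e.key_b, e.res_a)
        engaging = e.kind in ENGAGEMENT_KINDS
        if _matches(rec_res, a_set):
            bucket = anchor
            anchor_engaged |= engaging
        elif _matches(rec_res, v_set):
            bucket = activation
            activation_engaged |= engaging
        else:
            bucket = other
        if rec_res.key not in bucket[lig_key]:
            bucket[lig_key].append(rec_res.key)
    return RegionContactReport(
        anchor_contacts=anchor, activation_contacts=activation,
        other_contacts=other, anchor_engaged=anchor_engaged,
        activation_engaged=activation_engaged)


@dataclass
class NetworkComparison:
    shared: list[tuple]
    only_a: list[tuple]
    only_b: list[tuple]


def compare_networks(a: ResidueInteractionNetwork,
                     b: ResidueInteractionNetwork) -> NetworkComparison:
    """Shared and unique receptor-ligand edges of two networks.

    Edge identity is (kind, receptor residue, ligand residue) keyed on
    residue (chain, seq_num, icode).
    """
    def keyset(rin):
        lig = set(rin.ligand_keys())
        out = set()
        for e in rin.receptor_ligand_edges():
            lig_key, rec_key = ((e.key_a, e.key_b) if e.key_a in lig
                                else (e.key_b, e.key_a))
            out.add((e.kind, rec_key, lig_key))
        return out

    ka, kb = keyset(a), keyset(b)
    return NetworkComparison(shared=sorted(ka & kb),
                             only_a=sorted(ka - kb),
                             only_b=sorted(kb - ka))
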