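"""Interaction-network assembly at residue, domain and protein granularity.

Networks are simple undirected graphs (networkx) whose nodes carry a class
annotation (``histone:H3``, ``partner``, ``dna``) and whose edges carry an
interaction class and an evidence set (``structural:<pdb id>``,
``crosslink``, ``highthroughput``).  Residue-level nodes are
``<protein>/<sequence position>``; collapsing to domain or protein
granularity keeps an edge between two collapsed nodes iff at least one
residue-level edge exists between their members, with evidence unioned.

Evidence sources can be merged into a combined network and extended by one
additional layer of partner–partner edges into the global network used for
hub analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from histonet.exceptions import (
    GranularityMismatchError,
    NodeClassConflictError,
)
from histonet.interfaces import FOUR_CLASSES, ResidueContactEdge

logger = logging.getLogger(__name__)

GRANULARITIES = ("residue", "domain", "protein")


@dataclass
class Network:
    """Annotated simple graph at one granularity."""

    granularity: str
    provenance: str = "structural"
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"unknown granularity {self.granularity!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, node_id: str, node_class: str, **attrs) -> None:
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing.get("node_class") not in (
            None, node_class,
        ):
            raise NodeClassConflictError(
                f"node {node_id!r}: class {existing['node_class']!r} vs {node_class!r}"
            )
        self.graph.add_node(node_id, node_class=node_class, **attrs)

    def add_edge(
        self,
        a: str,
        b: str,
        interaction_class: str | None,
        evidence: set[str],
    ) -> None:
        if a == b:
            return  # simple graph: no self-loops
        if self.graph.has_edge(a, b):
            data = self.graph.edges[a, b]
            data["evidence"] = set(data["evidence"]) | set(evidence)
            if data.get("interaction_class") is None:
                data["interaction_class"] = interaction_class
        else:
            self.graph.add_edge(
                a, b,
                interaction_class=interaction_class,
                evidence=set(evidence),
            )

    def edges_of_class(self, interaction_class: str):
        return [
            (a, b) for a, b, d in self.graph.edges(data=True)
            if d.get("interaction_class") == interaction_class
        ]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, d in self.graph.edges(data=True):
            cls = d.get("interaction_class") or "unclassified"
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    def copy(self) -> "Network":
        new = Network(self.granularity, self.provenance, self.graph.copy())
        for a, b in new.graph.edges():
            new.graph.edges[a, b]["evidence"] = set(
                new.graph.edges[a, b]["evidence"]
            )
        return new


# ---------------------------------------------------------------------------
# construction from structural edges

def residue_node_id(protein: str, seq_pos: int) -> str:
    return f"{protein}/{seq_pos}"


def build_residue_network(
    edge_tables: list[list[ResidueContactEdge]],
    provenance: str = "structural",
    include_excluded_classes: bool = False,
) -> Network:
    """Residue-level network from classified edges of one or more structures.

    Duplicate edges across structures are merged with accumulated
    ``structural:<id>`` evidence.  Edges whose endpoints lack a sequence
    position are dropped (counted in the log).  Partner–partner and DNA–DNA
    contacts are excluded unless requested.
    """
    net = Network("residue", provenance=provenance)
    dropped = 0
    for edges in edge_tables:
        for e in edges:
            if e.interaction_class not in FOUR_CLASSES and not include_excluded_classes:
                continue
            if e.seq_pos_a is None or e.seq_pos_b is None:
                dropped += 1
                continue
            node_a = residue_node_id(e.protein_a, e.seq_pos_a)
            node_b = residue_node_id(e.protein_b, e.seq_pos_b)
            net.add_node(node_a, e.node_class_a, protein=e.protein_a,
                         seq_pos=e.seq_pos_a)
            net.add_node(node_b, e.node_class_b, protein=e.protein_b,
                         seq_pos=e.seq_pos_b)
            net.add_edge(
                node_a, node_b, e.interaction_class,
                {f"structural:{e.structure_id}"},
            )
    if dropped:
        logger.info("dropped %d edges lacking sequence positions", dropped)
    return net


def _class_pair_to_interaction(class_a: str, class_b: str) -> str | None:
    kinds = []
    for c in (class_a, class_b):
        kinds.append("histone" if c.startswith("histone") else c)
    roles = frozenset(kinds)
    return {
        frozenset(["histone"]): "HHI",
        frozenset(["histone", "dna"]): "HDI",
        frozenset(["histone", "partner"]): "HPI",
        frozenset(["partner", "dna"]): "DPI",
        frozenset(["partner"]): None,
        frozenset(["dna"]): None,
    }.get(roles)


def collapse_granularity(
    network: Network,
    to: str = "protein",
    domain_map: dict[str, list[tuple[int, int, str]]] | None = None,
) -> Network:
    """Collapse a residue network to domain or protein granularity.

    ``domain_map`` maps a partner protein id to ``(start, end, family)``
    ranges in sequence coordinates; partner residues falling outside any
    range (or proteins absent from the map) collapse to the whole-protein
    node.  Histone and DNA nodes always collapse to their protein-level
    node.  An edge exists between collapsed nodes iff at least one
    residue-level edge exists between their members; evidence is unioned.
    """
    if network.granularity != "residue":
        raise GranularityMismatchError("collapse starts from a residue network")
    if to not in ("domain", "protein"):
        raise ValueError("collapse target must be 'domain' or 'protein'")
    domain_map = domain_map or {}

    def collapsed(node_id: str, data: dict) -> tuple[str, str]:
        protein = data.get("protein", node_id.rsplit("/", 1)[0])
        node_class = data["node_class"]
        if to == "protein" or not node_class == "partner":
            return protein, node_class
        seq_pos = data.get("seq_pos")
        for (start, end, family) in domain_map.get(protein, []):
            if seq_pos is not None and start <= seq_pos <= end:
                return f"{protein}:{family}", node_class
        return protein, node_class

    out = Network(to, provenance=network.provenance)
    mapping: dict[str, str] = {}
    for node_id, data in network.graph.nodes(data=True):
        new_id, node_class = collapsed(node_id, data)
        mapping[node_id] = new_id
        out.add_node(new_id, node_class)
    for a, b, d in network.graph.edges(data=True):
        ca, cb = mapping[a], mapping[b]
        if ca == cb:
            continue
        cls = _class_pair_to_interaction(
            out.graph.nodes[ca]["node_class"], out.graph.nodes[cb]["node_class"]
        )
        out.add_edge(ca, cb, cls, set(d["evidence"]))
    return out


def build_protein_network_from_pairs(
    pairs: list[tuple[str, str]],
    node_classes: dict[str, str],
    provenance: str,
) -> Network:
    """Protein-level network from an external (e.g. crosslink/high-throughput)
    edge list; evidence tag = provenance."""
    net = Network("protein", provenance=provenance)
    for a, b in pairs:
        net.add_node(a, node_classes.get(a, "partner"))
        net.add_node(b, node_classes.get(b, "partner"))
        cls = _class_pair_to_interaction(
            net.graph.nodes[a]["node_class"], net.graph.nodes[b]["node_class"]
        )
        net.add_edge(a, b, cls, {provenance})
    return net


def merge_networks(nets: list[Network]) -> Network:
    """Union of same-granularity networks with evidence provenance preserved."""
    if not nets:
        raise ValueError("nothing to merge")
    gran = nets[0].granularity
    for net in nets[1:]:
        if net.granularity != gran:
            raise GranularityMismatchError(
                f"cannot merge {net.granularity} into {gran}"
            )
    out = Network(gran, provenance="combined")
    for net in nets:
        for node_id, data in net.graph.nodes(data=True):
            out.add_node(node_id, data["node_class"])
        for a, b, d in net.graph.edges(data=True):
            out.add_edge(a, b, d.get("interaction_class"), set(d["evidence"]))
    return out


def expand_global(
    network: Network,
    secondary_edges: list[tuple[str, str]],
    evidence_tag: str = "highthroughput",
) -> Network:
    """Add one layer of partner-of-partner edges to form the global network.

    A secondary edge is kept iff at least one endpoint already exists as a
    partner node; new endpoints enter as partners.  Nothing is ever removed.
    """
    out = network.copy()
    out.provenance = "global"
    existing_partners = {
        n for n, d in network.graph.nodes(data=True)
        if d.get("node_class") == "partner"
    }
    dropped = 0
    for a, b in secondary_edges:
        if a not in existing_partners and b not in existing_partners:
            dropped += 1
            continue
        for n in (a, b):
            if n not in out.graph:
                out.add_node(n, "partner")
        out.add_edge(a, b, None, {evidence_tag})
    if dropped:
        logger.info("expand_global: dropped %d unanchored secondary edges", dropped)
    return out


def compare_networks(a: Network, b: Network) -> dict[str, object]:
    """DyNet-style pairwise comparison: shared/unique nodes and shared edges."""
    nodes_a, nodes_b = set(a.graph.nodes), set(b.graph.nodes)
    edges_a = {frozenset(e) for e in a.graph.edges}
    edges_b = {frozenset(e) for e in b.graph.edges}
    shared_nodes = nodes_a & nodes_b
    shared_edges = edges_a & edges_b
    return {
        "shared_nodes": shared_nodes,
        "only_a": nodes_a - nodes_b,
        "only_b": nodes_b - nodes_a,
        "shared_edges": shared_edges,
        "n_shared_nodes": len(shared_nodes),
        "n_only_a": len(nodes_a - nodes_b),
        "n_only_b": len(nodes_b - nodes_a),
        "n_shared_edges": len(shared_edges),
    }


# ---------------------------------------------------------------------------
# export / import

def to_sif(network: Network, path: str | Path) -> None:
    """Cytoscape SIF export: nodeA <tab> interaction_class <tab> nodeB."""
    with open(path, "w") as fh:
        for a, b, d in sorted(network.graph.edges(data=True)):
            cls = d.get("interaction_class") or "interacts"
            fh.write(f"{a}\t{cls}\t{b}\n")


def to_tables(network: Network) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(node table, edge table) DataFrames for TSV export."""
    nodes = pd.DataFrame(
        [
            {"node_id": n, "node_class": d.get("node_class", "")}
            for n, d in sorted(network.graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "node_a": a,
                "node_b": b,
                "interaction_class": d.get("interaction_class") or "",
                "evidence": ";".join(sorted(d.get("evidence", ()))),
            }
            for a, b, d in sorted(network.graph.edges(data=True))
        ]
    )
    return nodes, edges


def to_json(network: Network, path: str | Path | None = None) -> dict:
    payload = {
        "granularity": network.granularity,
        "provenance": network.provenance,
        "nodes": [
            {"id": n, "node_class": d.get("node_class", "")}
            for n, d in sorted(network.graph.nodes(data=True))
        ],
        "edges": [
            {
                "a": a, "b": b,
                "interaction_class": d.get("interaction_class"),
                "evidence": sorted(d.get("evidence", ())),
            }
            for a, b, d in sorted(network.graph.edges(data=True))
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def from_json(source: str | Path | dict) -> Network:
    if not isinstance(source, dict):
        source = json.loads(Path(source).read_text())
    net = Network(source["granularity"], provenance=source["provenance"])
    for node in source["nodes"]:
        net.add_node(node["id"], node["node_class"])
    for edge in source["edges"]:
        net.add_edge(
            edge["a"], edge["b"], edge.get("interaction_class"),
            set(edge.get("evidence", ())),
        )
    return net
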