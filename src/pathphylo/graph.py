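"""Pathway graph data model.

A :class:`PathwayGraph` is the in-memory form of one species-specific
pathway: an undirected simple graph whose nodes carry cross-species
member identifiers.  Directed or repeated relations from source
documents are collapsed upstream (at parse time), so the total degree of
a node is simply its number of distinct neighbours.

The graph is backed by :class:`networkx.Graph`; nodes are integers local
to one graph, cross-species identity lives exclusively in the
``member_ids`` node attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .errors import ValidationError

NODE_CLASSES = ("gene", "compound", "group-derived")


@dataclass
class PathwayGraph:
    """Undirected simple graph of pathway members for one species.

    Parameters
    ----------
    species_code:
        Short species identifier (KEGG-style 3-4 letter code).
    g:
        Backing ``networkx.Graph``.  Node attributes: ``member_ids``
        (non-empty ``frozenset`` of strings for gene-class nodes) and
        ``node_class`` (one of ``gene``, ``compound``,
        ``group-derived``).  Optional edge attribute: ``subtype``.
    """

    species_code: str
    g: nx.Graph = field(default_factory=nx.Graph)

    # -- construction ------------------------------------------------

    @classmethod
    def build(
        cls,
        species_code: str,
        nodes: Iterable[tuple[int, Iterable[str], str]] | Iterable[tuple[int, Iterable[str]]],
        edges: Iterable[tuple] = (),
    ) -> "PathwayGraph":
        """Build and validate a graph from node and edge records.

        ``nodes`` yields ``(node_id, member_ids[, node_class])``;
        ``edges`` yields ``(u, v[, subtype])``.
        """
        g = nx.Graph()
        for rec in nodes:
            node_id, member_ids = rec[0], frozenset(rec[1])
            node_class = rec[2] if len(rec) > 2 else "gene"
            if node_id in g:
                raise ValidationError(f"duplicate node_id {node_id!r}")
            if node_class not in NODE_CLASSES:
                raise ValidationError(f"unknown node_class {node_class!r}")
            if node_class == "gene" and not member_ids:
                raise ValidationError(
                    f"gene-class node {node_id!r} has empty member_ids"
                )
            g.add_node(node_id, member_ids=member_ids, node_class=node_class)
        for rec in edges:
            u, v = rec[0], rec[1]
            subtype = rec[2] if len(rec) > 2 else None
            if u not in g or v not in g:
                raise ValidationError(f"edge ({u!r}, {v!r}) references unknown node")
            if u == v:
                raise ValidationError(f"self-loop on node {u!r} not allowed")
            g.add_edge(u, v, subtype=subtype)
        return cls(species_code, g)

    # -- elementary queries ------------------------------------------

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.g.nodes)

    def member_ids(self, node_id: int) -> frozenset[str]:
        self._check_node(node_id)
        return self.g.nodes[node_id]["member_ids"]

    def node_class(self, node_id: int) -> str:
        self._check_node(node_id)
        return self.g.nodes[node_id].get("node_class", "gene")

    def all_member_ids(self) -> frozenset[str]:
        """Union of member identifiers over all nodes."""
        out: set[str] = set()
        for n in self.g.nodes:
            out |= self.g.nodes[n]["member_ids"]
        return frozenset(out)

    def _check_node(self, node_id: int) -> None:
        if node_id not in self.g:
            raise ValidationError(
                f"node {node_id!r} not in graph of {self.species_code!r}"
            )

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    def edge_set(self) -> frozenset[frozenset[int]]:
        return frozenset(frozenset(e) for e in self.g.edges)


@dataclass(frozen=True)
class DegreeReport:
    """Per-node total degrees and their maximum (0 for empty graphs)."""

    degrees: Mapping[int, int]
    max_total_degree: int


def total_degree(graph: PathwayGraph, node_id: int) -> int:
    """Number of incident edges of ``node_id`` (= distinct neighbours)."""
    graph._check_node(node_id)
    return graph.g.degree[node_id]


def max_total_degree(graph: PathwayGraph) -> int:
    """Highest total degree of any node; 0 for node- or edge-free graphs."""
    if graph.g.number_of_nodes() == 0:
        return 0
    return max(d for _, d in graph.g.degree)


def degree_report(graph: PathwayGraph) -> DegreeReport:
    degrees = {n: graph.g.degree[n] for n in graph.g.nodes}
    return DegreeReport(degrees=degrees, max_total_degree=max_total_degree(graph))


def connected_components(graph: PathwayGraph) -> list[frozenset[int]]:
    """Maximal connected node sets, ordered by smallest contained node_id."""
    comps = [frozenset(c) for c in nx.connected_components(graph.g)]
    return sorted(comps, key=min)


# -- interchange dialect ---------------------------------------------


def write_graph_tsv(graph: PathwayGraph, edge_path, node_path) -> None:
    """Write the package's interchange dialect.

    Edge list: ``node1<TAB>node2<TAB>subtype`` and node table:
    ``node_id<TAB>node_class<TAB>member_ids`` (comma-joined).
    """
    with open(edge_path, "w") as fh:
        fh.write("node1\tnode2\tsubtype\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.g.edges):
            subtype = graph.g.edges[u, v].get("subtype") or ""
            fh.write(f"{u}\t{v}\t{subtype}\n")
    with open(node_path, "w") as fh:
        fh.write("node_id\tnode_class\tmember_ids\n")
        for n in graph.node_ids:
            members = ",".join(sorted(graph.g.nodes[n]["member_ids"]))
            fh.write(f"{n}\t{graph.node_class(n)}\t{members}\n")


def read_graph_tsv(species_code: str, edge_path, node_path) -> PathwayGraph:
    """Read the interchange dialect written by :func:`write_graph_tsv`."""
    nodes = []
    with open(node_path) as fh:
        header = fh.readline()
        if not header.startswith("node_id"):
            raise ValidationError(f"bad node table header in {node_path}")
        for line in fh:
            if not line.strip():
                continue
            node_id, node_class, members = line.rstrip("\n").split("\t")
            member_ids = [m for m in members.split(",") if m]
            nodes.append((int(node_id), member_ids, node_class))
    edges = []
    with open(edge_path) as fh:
        header = fh.readline()
        if not header.startswith("node1"):
            raise ValidationError(f"bad edge list header in {edge_path}")
        for line in fh:
            if not line.strip():
                continue
            u, v, subtype = line.rstrip("\n").split("\t")
            edges.append((int(u), int(v), subtype or None))
    return PathwayGraph.build(species_code, nodes, edges)
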