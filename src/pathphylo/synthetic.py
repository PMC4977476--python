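"""Synthetic pathway families with known phylogenetic structure.

Emulates a family of species-specific pathway graphs produced by gene
gain and loss along a known (planted) phylogeny: an ancestral random
connected pathway evolves along each branch through Poisson-distributed
node losses, node gains and edge rewires, with rates expressed as
expected events per unit branch length.  Member identifiers are drawn
from one global namespace ("K0001"-style), so cross-species module
intersections are exact by construction.  Every leaf graph can also be
emitted as a valid KGML document, making the whole pipeline testable
without any external download.

What this emulates — and what it does not: real pathway annotations
drift by curation effort as well as by evolution, pathway graphs are
far from Erdos-Renyi, and real orthology mapping is noisy.  The
generator provides clean, seedable ground truth for method validation,
not a fitted model of any database's content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ValidationError
from .graph import PathwayGraph
from .trees import write_newick

DEFAULT_ANCESTOR_SIZE = 40
DEFAULT_EDGE_DENSITY = 0.15
DEFAULT_LOSS_RATE = 0.08
DEFAULT_GAIN_RATE = 0.08
DEFAULT_REWIRE_RATE = 0.0
#: default planted-tree branch lengths, in the time units of the event
#: rates.  Internal branches carry the topological signal (60 units x
#: 0.08 events/unit gives ~4.8 expected gains+losses per branch, so
#: P(an internal branch leaves no trace) < 0.01); pendant branches are
#: kept short because terminal events are phylogenetically
#: uninformative noise — the regime of a densely sampled clade.
DEFAULT_INTERNAL_BRANCH = 60.0
DEFAULT_PENDANT_BRANCH = 20.0


@dataclass
class EvolutionConfig:
    """Study conditions for one simulated pathway family."""

    planted_tree: dendropy.Tree
    ancestor_size: int = DEFAULT_ANCESTOR_SIZE
    ancestor_edge_density: float = DEFAULT_EDGE_DENSITY
    loss_rate: float = DEFAULT_LOSS_RATE
    gain_rate: float = DEFAULT_GAIN_RATE
    rewire_rate: float = DEFAULT_REWIRE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "gain_rate", "rewire_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.ancestor_size < 1:
            raise ValidationError("ancestor_size must be >= 1")


@dataclass
class PathwayFamily:
    """Planted tree, per-leaf graphs, and the per-branch event log."""

    planted_tree: dendropy.Tree
    leaf_graphs: dict[str, PathwayGraph]
    event_log: list[dict] = field(default_factory=list)


def random_graph(
    n: int, edge_probability: float, seed, species_code: str = "syn"
) -> PathwayGraph:
    """Erdos-Renyi-style simple pathway graph, reproducible from seed."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    if not 0.0 <= edge_probability <= 1.0:
        raise ValidationError("edge_probability must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [(i, [f"K{i + 1:04d}"], "gene") for i in range(n)]
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < edge_probability
    ]
    return PathwayGraph.build(species_code, nodes, edges)


def random_planted_tree(
    n_leaves: int,
    seed,
    internal_branch: float = DEFAULT_INTERNAL_BRANCH,
    pendant_branch: float = DEFAULT_PENDANT_BRANCH,
) -> dendropy.Tree:
    """Random binary planted tree with fixed branch lengths by branch class.

    Topology by uniformly random joins; internal branches get
    ``internal_branch`` time units and pendant (leaf) branches get
    ``pendant_branch``.
    """
    if n_leaves < 3:
        raise ValidationError("planted tree needs at least 3 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"s{i + 1:02d}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    lineages = [(dendropy.Node(taxon=taxa.get_taxon(lab)), True) for lab in labels]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, a_is_leaf), (b, b_is_leaf) = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a)
        a.edge.length = pendant_branch if a_is_leaf else internal_branch
        parent.add_child(b)
        b.edge.length = pendant_branch if b_is_leaf else internal_branch
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append((parent, False))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=lineages[0][0])
    tree.is_rooted = False
    return tree


def _evolve_branch(
    graph: PathwayGraph,
    length: float,
    config: EvolutionConfig,
    rng: np.random.Generator,
    next_member: list[int],
    log: list[dict],
    branch_label: str,
) -> PathwayGraph:
    g = graph.g.copy()
    n_loss = rng.poisson(config.loss_rate * length)
    n_gain = rng.poisson(config.gain_rate * length)
    n_rewire = rng.poisson(config.rewire_rate * length)
    events = {"branch": branch_label, "losses": [], "gains": [], "rewires": 0}

    for _ in range(n_loss):
        if g.number_of_nodes() <= 3:
            raise ValidationError(
                "loss rate too high: a leaf graph would shrink below 3 nodes; "
                "lower loss_rate or shorten branches"
            )
        victim = sorted(g.nodes)[rng.integers(g.number_of_nodes())]
        events["losses"].append(sorted(g.nodes[victim]["member_ids"]))
        g.remove_node(victim)

    for _ in range(n_gain):
        member = f"K{next_member[0]:04d}"
        next_member[0] += 1
        new_id = max(g.nodes, default=-1) + 1
        hosts = sorted(g.nodes)
        # preferential attachment: hubs persist, so modules keep structure
        weights = np.array([g.degree[h] + 1 for h in hosts], dtype=float)
        weights /= weights.sum()
        k = min(int(rng.integers(1, 4)), len(hosts))
        chosen = rng.choice(len(hosts), size=k, replace=False, p=weights)
        g.add_node(new_id, member_ids=frozenset({member}), node_class="gene")
        for idx in chosen:
            g.add_edge(hosts[idx], new_id, subtype=None)
        events["gains"].append(member)

    for _ in range(n_rewire):
        edges = sorted(tuple(sorted(e)) for e in g.edges)
        if not edges:
            break
        u, v = edges[rng.integers(len(edges))]
        candidates = sorted(set(g.nodes) - set(g.neighbors(u)) - {u})
        if not candidates:
            continue
        w = candidates[rng.integers(len(candidates))]
        g.remove_edge(u, v)
        g.add_edge(u, w, subtype=None)
        events["rewires"] += 1

    log.append(events)
    return PathwayGraph(graph.species_code, g)


def simulate_family(config: EvolutionConfig) -> PathwayFamily:
    """Evolve an ancestral pathway along the planted tree.

    The ancestor is a random connected graph (regenerated until
    connected); each branch applies Poisson(rate x length) losses,
    gains and rewires.  Fully reproducible from ``config.seed``.
    """
    tree = config.planted_tree
    leaves = [l for l in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValidationError("planted tree needs at least 3 leaves")
    rng = np.random.default_rng(config.seed)

    ancestor = None
    for _ in range(1000):
        candidate = random_graph(
            config.ancestor_size, config.ancestor_edge_density, rng, "ancestor"
        )
        import networkx as nx

        if candidate.g.number_of_nodes() > 0 and nx.is_connected(candidate.g):
            ancestor = candidate
            break
    if ancestor is None:
        raise ValidationError(
            "could not generate a connected ancestor; raise edge density"
        )

    next_member = [config.ancestor_size + 1]
    log: list[dict] = []
    leaf_graphs: dict[str, PathwayGraph] = {}

    def recurse(node, graph: PathwayGraph, path: str) -> None:
        children = node.child_nodes()
        if not children:
            label = node.taxon.label
            leaf_graphs[label] = PathwayGraph(label, graph.g)
            return
        for idx, child in enumerate(children):
            length = child.edge.length or 0.0
            branch_label = f"{path}.{idx}"
            evolved = _evolve_branch(
                graph, length, config, rng, next_member, log, branch_label
            )
            recurse(child, evolved, branch_label)

    recurse(tree.seed_node, ancestor, "root")
    return PathwayFamily(planted_tree=tree, leaf_graphs=leaf_graphs, event_log=log)


# -- KGML emission ---------------------------------------------------


def emit_kgml(graph: PathwayGraph, pathway_name: str = "synthetic") -> str:
    """Serialize a pathway graph as a KGML document.

    Round-trips through :func:`pathphylo.kgml.parse_kgml` (gene nodes
    always; compound nodes require ``include_compounds``).  Member
    identifiers are emitted species-prefixed, the way KEGG names them.
    """
    from lxml import etree

    root = etree.Element(
        "pathway",
        name=f"path:{graph.species_code}_{pathway_name}",
        org=graph.species_code,
        title=pathway_name,
    )
    for n in graph.node_ids:
        names = " ".join(
            f"{graph.species_code}:{m}" for m in sorted(graph.member_ids(n))
        )
        kind = "gene" if graph.node_class(n) != "compound" else "compound"
        etree.SubElement(root, "entry", id=str(n), name=names, type=kind)
    for u, v in sorted(tuple(sorted(e)) for e in graph.g.edges):
        rel = etree.SubElement(
            root, "relation", entry1=str(u), entry2=str(v), type="PPrel"
        )
        subtype = graph.g.edges[u, v].get("subtype")
        if subtype:
            etree.SubElement(rel, "subtype", name=subtype, value="")
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def write_family(family: PathwayFamily, outdir) -> None:
    """Write per-leaf KGML files, the planted Newick tree, and the event log."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for label, graph in sorted(family.leaf_graphs.items()):
        (out / f"{label}.xml").write_text(emit_kgml(graph))
    write_newick(family.planted_tree, out / "planted.nwk")
    (out / "events.json").write_text(json.dumps(family.event_log, indent=2) + "\n")
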