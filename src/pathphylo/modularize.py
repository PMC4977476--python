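"""Pathway modularization.

Decomposes a pathway graph into modules — subgraphs that tend to be
self-sufficient, keeping most of their edges internal — controlled by a
user-defined granularity factor ``c``.  The legal range of ``c`` is
``1 .. max_total_degree`` of the graph.

The default strategy is degree-seeded synchronous label propagation:

1. every node with total degree >= ``c`` seeds its own module;
2. rounds of synchronous propagation: each unassigned node adjacent to
   at least one module joins the module to which it has most edges
   (ties: the module containing its highest-degree assigned neighbour,
   then the module with the smallest member identifier);
3. every connected component without a seed becomes one whole module
   (isolated nodes thus become singleton modules).

The resulting modules form a partition of the node set, each module's
induced subgraph is connected, and the outcome is independent of node
iteration order.  The entry point takes a config object naming the
strategy so that alternative modularization policies can be added
without touching the distance computations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError
from .graph import PathwayGraph, connected_components, max_total_degree

DEFAULT_C = 3


@dataclass(frozen=True)
class ModularizationConfig:
    """Granularity factor ``c`` and the (fixed) deterministic tie rule."""

    c: int = DEFAULT_C
    tie_rule: str = "edges-neighbor-degree-lexicographic"


@dataclass(frozen=True)
class ModuleSet:
    """Ordered modules of one species' pathway.

    ``modules`` holds node-id sets partitioning the graph;
    ``member_view`` holds, per module, the union of member identifiers
    of its nodes — the sets entering the cross-species similarity.
    """

    species_code: str
    modules: tuple[frozenset[int], ...]
    member_view: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.modules)


def module_count(mset: ModuleSet) -> int:
    """Number of modules (m1/m2 of the species-similarity grid)."""
    return len(mset.modules)


def single_module_set(graph: PathwayGraph) -> ModuleSet:
    """Degenerate control: the whole pathway as one module."""
    nodes = frozenset(graph.g.nodes)
    if not nodes:
        return ModuleSet(graph.species_code, (), ())
    return ModuleSet(
        graph.species_code, (nodes,), (graph.all_member_ids(),)
    )


def modularize(graph: PathwayGraph, config: ModularizationConfig | int) -> ModuleSet:
    """Partition ``graph`` into connected modules at granularity ``c``.

    Raises
    ------
    ValidationError
        If ``c`` lies outside ``[1, max_total_degree]`` (checked only
        when the graph has at least one edge).
    """
    if isinstance(config, int):
        config = ModularizationConfig(c=config)
    c = config.c
    maxdeg = max_total_degree(graph)
    if graph.g.number_of_edges() > 0 and not 1 <= c <= maxdeg:
        raise ValidationError(
            f"factor c={c} outside the legal interval [1, {maxdeg}] "
            f"for graph {graph.species_code!r}"
        )

    g = graph.g
    degree = dict(g.degree)
    # min member identifier per node, for deterministic tie-breaking
    node_min_member = {
        n: min(g.nodes[n]["member_ids"]) if g.nodes[n]["member_ids"] else ""
        for n in g.nodes
    }

    assignment: dict[int, int] = {}
    module_min_member: dict[int, str] = {}
    seeds = sorted(n for n in g.nodes if degree[n] >= c)
    for idx, s in enumerate(seeds):
        assignment[s] = idx
        module_min_member[idx] = node_min_member[s]

    # synchronous propagation: decisions in one round see only the
    # previous round's assignment, so iteration order cannot matter
    changed = True
    while changed:
        changed = False
        joins: list[tuple[int, int]] = []
        for n in g.nodes:
            if n in assignment:
                continue
            candidates: dict[int, list] = {}
            for nbr in g.neighbors(n):
                mod = assignment.get(nbr)
                if mod is None:
                    continue
                rec = candidates.setdefault(mod, [0, -1])
                rec[0] += 1                              # edges into module
                rec[1] = max(rec[1], degree[nbr])        # best neighbour degree
            if not candidates:
                continue
            best = min(
                candidates.items(),
                key=lambda kv: (-kv[1][0], -kv[1][1], module_min_member[kv[0]], kv[0]),
            )[0]
            joins.append((n, best))
        for n, mod in joins:
            assignment[n] = mod
            module_min_member[mod] = min(module_min_member[mod], node_min_member[n])
            changed = True

    # seedless components (including isolated nodes) form whole modules
    next_idx = len(seeds)
    for comp in connected_components(graph):
        if not any(n in assignment for n in comp):
            for n in comp:
                assignment[n] = next_idx
            next_idx += 1

    grouped: dict[int, set[int]] = {}
    for n, mod in assignment.items():
        grouped.setdefault(mod, set()).add(n)

    modules = []
    for nodes in grouped.values():
        members = frozenset().union(*(g.nodes[n]["member_ids"] for n in nodes))
        modules.append((frozenset(nodes), members))
    # deterministic order: by smallest member identifier, then node id
    modules.sort(key=lambda m: (min(m[1]) if m[1] else "", min(m[0])))

    return ModuleSet(
        species_code=graph.species_code,
        modules=tuple(m[0] for m in modules),
        member_view=tuple(m[1] for m in modules),
    )


def write_modules_tsv(mset: ModuleSet, path) -> None:
    """Write ``species<TAB>module_index<TAB>member_id`` rows."""
    with open(path, "w") as fh:
        fh.write("species\tmodule_index\tmember_id\n")
        for idx, members in enumerate(mset.member_view):
            for m in sorted(members):
                fh.write(f"{mset.species_code}\t{idx}\t{m}\n")
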