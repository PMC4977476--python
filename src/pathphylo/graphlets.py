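"""Graphlet degree signatures.

A graphlet is a small connected induced subgraph on 2-5 nodes; there
are 30 of them and their nodes fall into 73 automorphism orbits.  The
graphlet degree signature of a node is the 73-vector counting, per
orbit, how many graphlet occurrences touch the node at that orbit.
Orbit 0 is the plain degree (occurrences of the single edge).

The atlas of graphlets and orbits is generated at import time from
first principles: all connected graphs on 2-5 nodes are enumerated,
canonicalized, and ordered by (node count, edge count, descending
degree sequence, canonical form); orbits within a graphlet are ordered
by (degree, sorted neighbour degrees, triangle count, distance
profile).  For graphlets up to 4 nodes this reproduces the standard
published orbit numbering (0-14); the 5-node orbits follow the same
deterministic rule.

Signature similarity follows the graphlet-degree scheme of the
seed-and-extend aligner this package's pathway distance is built on:
per-orbit distances are logarithmic and each orbit is weighted by
``w_i = 1 - log(o_i)/log(73)`` where ``o_i`` counts the orbits that
affect orbit i (the distinct orbits its representative node touches
within the orbit's own graphlet); the dependency counts are computed
from the atlas rather than transcribed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ValidationError
from .graph import PathwayGraph

N_ORBITS = 73
N_GRAPHLETS = 30
MAX_GRAPHLET_NODES = 5


# -- small-graph utilities (graphs as local adjacency bitmasks) ------


def _adj_from_edges(n: int, edges) -> tuple[int, ...]:
    adj = [0] * n
    for u, v in edges:
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    return tuple(adj)


def _is_connected(n: int, adj) -> bool:
    if n == 0:
        return False
    seen = 1
    stack = [0]
    while stack:
        u = stack.pop()
        new = adj[u] & ~seen
        while new:
            b = new & -new
            seen |= b
            stack.append(b.bit_length() - 1)
            new ^= b
    return seen == (1 << n) - 1


def _canonical_edges(n: int, edges) -> tuple[tuple[int, int], ...]:
    """Minimum edge tuple over all node relabelings."""
    best = None
    for perm in itertools.permutations(range(n)):
        remapped = tuple(
            sorted(tuple(sorted((perm[u], perm[v]))) for u, v in edges)
        )
        if best is None or remapped < best:
            best = remapped
    return best


def _node_invariants(n: int, adj):
    """Per-node tuple (degree, sorted nbr degrees, triangles, distance profile)."""
    degs = [bin(a).count("1") for a in adj]
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i] >> j & 1]
        tri = sum(
            1
            for a, b in itertools.combinations(nbrs, 2)
            if adj[a] >> b & 1
        )
        # BFS distances
        dist = [-1] * n
        dist[i] = 0
        frontier = [i]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in range(n):
                    if adj[u] >> w & 1 and dist[w] < 0:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        out.append(
            (
                degs[i],
                tuple(sorted(degs[j] for j in nbrs)),
                tri,
                tuple(sorted(dist)),
            )
        )
    return out


def _graph_key(n: int, adj) -> tuple:
    """Isomorphism-invariant classification key (may have collisions)."""
    invs = _node_invariants(n, adj)
    m = sum(bin(a).count("1") for a in adj) // 2
    return (n, m, tuple(sorted(i[0] for i in invs)), tuple(sorted(i[2] for i in invs)))


# -- atlas -----------------------------------------------------------


@dataclass(frozen=True)
class Graphlet:
    """One of the 30 connected 2-5-node graphs, with its orbit structure."""

    index: int
    n: int
    edges: tuple[tuple[int, int], ...]
    orbit_of_node: tuple[int, ...]        # global orbit id per node 0..n-1
    orbit_ids: tuple[int, ...]            # distinct orbit ids, ascending


def _automorphism_orbits(n: int, edges) -> list[int]:
    """Partition nodes into automorphism classes; returns class index per node."""
    edge_set = frozenset(frozenset(e) for e in edges)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in itertools.permutations(range(n)):
        mapped = frozenset(frozenset((perm[u], perm[v])) for u, v in edges)
        if mapped == edge_set:
            for v in range(n):
                a, b = find(v), find(perm[v])
                if a != b:
                    parent[a] = b
    classes: dict[int, int] = {}
    out = []
    for v in range(n):
        r = find(v)
        if r not in classes:
            classes[r] = len(classes)
        out.append(classes[r])
    return out


def _build_atlas():
    graphlets_raw = []
    for n in range(2, MAX_GRAPHLET_NODES + 1):
        pairs = list(itertools.combinations(range(n), 2))
        seen = set()
        for mask in range(1 << len(pairs)):
            edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
            adj = _adj_from_edges(n, edges)
            if not _is_connected(n, adj):
                continue
            canon = _canonical_edges(n, edges)
            if canon in seen:
                continue
            seen.add(canon)
            canon_adj = _adj_from_edges(n, canon)
            degs_desc = tuple(sorted((bin(a).count("1") for a in canon_adj), reverse=True))
            graphlets_raw.append((n, len(canon), degs_desc, canon, canon_adj))
    # deterministic order: node count, edge count, descending degree
    # sequence (lexicographic), then canonical form
    graphlets_raw.sort(key=lambda g: (g[0], g[1], g[2], g[3]))

    graphlets: list[Graphlet] = []
    orbit_rep: list[tuple[int, int]] = []  # orbit id -> (graphlet index, node)
    next_orbit = 0
    for gi, (n, _m, _d, canon, adj) in enumerate(graphlets_raw):
        auto = _automorphism_orbits(n, canon)
        invs = _node_invariants(n, adj)
        # one representative node per automorphism class, ordered by invariant
        classes: dict[int, list[int]] = {}
        for v, c in enumerate(auto):
            classes.setdefault(c, []).append(v)
        ordered = sorted(classes.values(), key=lambda nodes: invs[nodes[0]])
        orbit_of_node = [-1] * n
        ids = []
        for nodes in ordered:
            for v in nodes:
                orbit_of_node[v] = next_orbit
            orbit_rep.append((gi, nodes[0]))
            ids.append(next_orbit)
            next_orbit += 1
        graphlets.append(
            Graphlet(gi, n, canon, tuple(orbit_of_node), tuple(ids))
        )
    if len(graphlets) != N_GRAPHLETS or next_orbit != N_ORBITS:
        raise AssertionError(
            f"graphlet atlas inconsistent: {len(graphlets)} graphlets, {next_orbit} orbits"
        )

    # classification tables
    by_key: dict[tuple, list[Graphlet]] = {}
    canon_lookup: dict[tuple, Graphlet] = {}
    orbit_lookup: dict[int, dict[tuple, int]] = {}
    for g in graphlets:
        adj = _adj_from_edges(g.n, g.edges)
        by_key.setdefault(_graph_key(g.n, adj), []).append(g)
        canon_lookup[g.edges] = g
        invs = _node_invariants(g.n, adj)
        table: dict[tuple, int] = {}
        for v in range(g.n):
            inv = invs[v]
            if inv in table and table[inv] != g.orbit_of_node[v]:
                raise AssertionError(
                    f"orbit invariant collision within graphlet {g.index}"
                )
            table[inv] = g.orbit_of_node[v]
        orbit_lookup[g.index] = table
    return graphlets, orbit_rep, by_key, canon_lookup, orbit_lookup


GRAPHLETS, _ORBIT_REP, _BY_KEY, _CANON_LOOKUP, _ORBIT_LOOKUP = _build_atlas()


def _classify(n: int, adj, edges) -> Graphlet:
    """Map a connected local graph to its graphlet (invariant key, canonical fallback)."""
    candidates = _BY_KEY.get(_graph_key(n, adj))
    if candidates is None:
        raise AssertionError("subgraph does not match any graphlet")
    if len(candidates) == 1:
        return candidates[0]
    return _CANON_LOOKUP[_canonical_edges(n, edges)]


def _classify_node(n: int, adj, edges, local_node: int) -> int:
    """Global orbit id of ``local_node`` within its connected local graph."""
    g = _classify(n, adj, edges)
    inv = _node_invariants(n, adj)[local_node]
    try:
        return _ORBIT_LOOKUP[g.index][inv]
    except KeyError:
        # exhaustive fallback: find an isomorphism onto the canonical form
        target = frozenset(frozenset(e) for e in g.edges)
        for perm in itertools.permutations(range(n)):
            if frozenset(frozenset((perm[u], perm[v])) for u, v in edges) == target:
                return g.orbit_of_node[perm[local_node]]
        raise AssertionError("no isomorphism found during orbit classification")


# -- orbit dependency weights ----------------------------------------


@lru_cache(maxsize=1)
def orbit_dependency_counts() -> tuple[int, ...]:
    """o_i: number of distinct orbits the representative node of orbit i
    touches across connected induced subgraphs of its own graphlet."""
    counts = []
    for gi, v in _ORBIT_REP:
        g = GRAPHLETS[gi]
        full_adj = _adj_from_edges(g.n, g.edges)
        touched: set[int] = set()
        others = [u for u in range(g.n) if u != v]
        for size in range(2, g.n + 1):
            for extra in itertools.combinations(others, size - 1):
                sub = (v,) + extra
                index = {node: i for i, node in enumerate(sub)}
                sub_edges = [
                    (index[a], index[b])
                    for a, b in g.edges
                    if a in index and b in index
                ]
                adj = _adj_from_edges(size, sub_edges)
                if not _is_connected(size, adj):
                    continue
                touched.add(_classify_node(size, adj, sub_edges, index[v]))
        counts.append(len(touched))
    return tuple(counts)


@lru_cache(maxsize=1)
def orbit_weights() -> np.ndarray:
    """w_i = 1 - log(o_i) / log(73)."""
    o = np.array(orbit_dependency_counts(), dtype=float)
    return 1.0 - np.log(o) / np.log(N_ORBITS)


# -- counting --------------------------------------------------------


@dataclass(frozen=True)
class GraphletSignature:
    """Orbit counts of one node (orbit 0 equals its total degree)."""

    node_id: int
    orbit_counts: tuple[int, ...]


def _connected_subsets(adj: dict, nodes: list, k: int):
    """Yield every connected induced node subset of size k exactly once (ESU)."""
    for v in nodes:
        ext = sorted(u for u in adj[v] if u > v)
        yield from _esu_extend([v], ext, v, adj, k)


def _esu_extend(sub: list, ext: list, root, adj: dict, k: int):
    if len(sub) == k:
        yield tuple(sub)
        return
    ext = list(ext)
    while ext:
        w = ext.pop()
        neighborhood = set().union(*(adj[s] for s in sub))
        new_ext = ext + [
            u for u in adj[w] if u > root and u not in neighborhood and u not in sub
        ]
        yield from _esu_extend(sub + [w], new_ext, root, adj, k)


def orbit_counts(graph: PathwayGraph) -> dict[int, np.ndarray]:
    """Per-node 73-orbit graphlet degree vectors.

    Counts every connected induced subgraph on 2-5 nodes once and
    increments, for each of its nodes, the orbit at which that node
    touches the corresponding graphlet.
    """
    g = graph.g
    nodes = sorted(g.nodes)
    adj = {n: set(g.neighbors(n)) for n in nodes}
    counts = {n: np.zeros(N_ORBITS, dtype=np.int64) for n in nodes}
    for k in range(2, MAX_GRAPHLET_NODES + 1):
        for sub in _connected_subsets(adj, nodes, k):
            index = {node: i for i, node in enumerate(sub)}
            sub_edges = [
                (index[a], index[b])
                for i, a in enumerate(sub)
                for b in sub[i + 1 :]
                if b in adj[a]
            ]
            local_adj = _adj_from_edges(k, sub_edges)
            glet = _classify(k, local_adj, sub_edges)
            invs = _node_invariants(k, local_adj)
            table = _ORBIT_LOOKUP[glet.index]
            for node, i in index.items():
                counts[node][table[invs[i]]] += 1
    return counts


def signatures(graph: PathwayGraph) -> dict[int, GraphletSignature]:
    return {
        n: GraphletSignature(n, tuple(int(x) for x in v))
        for n, v in orbit_counts(graph).items()
    }


def signature_similarity(sig_u, sig_v) -> float:
    """Weighted graphlet-degree similarity in [0, 1].

    Per-orbit distance |log(u+1) - log(v+1)| / log(max(u, v) + 2),
    weighted by the orbit dependency weights and normalized by their
    sum; similarity is one minus the mean distance.
    """
    u = np.asarray(
        sig_u.orbit_counts if isinstance(sig_u, GraphletSignature) else sig_u,
        dtype=float,
    )
    v = np.asarray(
        sig_v.orbit_counts if isinstance(sig_v, GraphletSignature) else sig_v,
        dtype=float,
    )
    if u.shape != (N_ORBITS,) or v.shape != (N_ORBITS,):
        raise ValidationError(
            f"signatures must have length {N_ORBITS}, got {u.shape} and {v.shape}"
        )
    w = orbit_weights()
    per_orbit = w * np.abs(np.log(u + 1.0) - np.log(v + 1.0)) / np.log(
        np.maximum(u, v) + 2.0
    )
    return float(1.0 - per_orbit.sum() / w.sum())
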