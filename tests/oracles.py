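"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or direct
evaluation, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools

import dendropy
import networkx as nx
import numpy as np

_CANON_CACHE: dict = {}


def _canonical_with_positions(k: int, edges: frozenset):
    """Canonical edge tuple and, per node, its canonical orbit position.

    The orbit position of node v is the minimum image of v over all
    permutations that realize the canonical form; nodes in the same
    automorphism orbit share it.
    """
    key = (k, edges)
    if key in _CANON_CACHE:
        return _CANON_CACHE[key]
    best = None
    best_perms = []
    for perm in itertools.permutations(range(k)):
        remapped = tuple(sorted(tuple(sorted((perm[u], perm[v]))) for u, v in edges))
        if best is None or remapped < best:
            best = remapped
            best_perms = [perm]
        elif remapped == best:
            best_perms.append(perm)
    pos = tuple(min(p[v] for p in best_perms) for v in range(k))
    _CANON_CACHE[key] = (best, pos)
    return best, pos


def orbit_key(k: int, local_edges, v_local: int):
    """Isomorphism-invariant (graphlet, orbit) label for one node."""
    canon, pos = _canonical_with_positions(k, frozenset(local_edges))
    return (canon, pos[v_local])


def naive_orbit_counts(g: nx.Graph):
    """Counts per (node, orbit_key) via itertools subset enumeration."""
    counts: dict = {n: {} for n in g.nodes}
    nodes = sorted(g.nodes)
    for k in range(2, 6):
        for sub in itertools.combinations(nodes, k):
            h = g.subgraph(sub)
            if not nx.is_connected(h):
                continue
            index = {n: i for i, n in enumerate(sub)}
            local_edges = [(index[a], index[b]) for a, b in h.edges]
            for n in sub:
                key = orbit_key(k, local_edges, index[n])
                d = counts[n]
                d[key] = d.get(key, 0) + 1
    return counts


def atlas_orbit_key_map():
    """Bijection between oracle orbit keys and the package's orbit ids."""
    from pathphylo.graphlets import GRAPHLETS

    mapping = {}
    for glet in GRAPHLETS:
        for v in range(glet.n):
            key = orbit_key(glet.n, glet.edges, v)
            oid = glet.orbit_of_node[v]
            assert mapping.get(key, oid) == oid, "orbit key collision"
            mapping[key] = oid
    assert len(set(mapping.values())) == 73
    return mapping


def naive_edge_correctness(g_edges, mapping, h: nx.Graph) -> float:
    """Per-edge loop over the first graph's edge list."""
    g_edges = list(g_edges)
    if not g_edges:
        return 1.0
    hits = sum(1 for u, v in g_edges if h.has_edge(mapping[u], mapping[v]))
    return hits / len(g_edges)


def brute_force_branch_matching(bips1, bips2) -> float:
    """Maximum total score over all zero-padded bijections (factorial search)."""
    from pathphylo.treecompare import branch_score

    n = max(len(bips1), len(bips2))
    grid = [[0.0] * n for _ in range(n)]
    for i, p in enumerate(bips1):
        for j, q in enumerate(bips2):
            grid[i][j] = branch_score(p, q)
    return max(
        sum(grid[i][perm[i]] for i in range(n))
        for perm in itertools.permutations(range(n))
    )


def random_binary_tree(n_leaves: int, seed, bl_low=0.05, bl_high=2.0) -> dendropy.Tree:
    """Random binary tree with uniform branch lengths (additive-test input)."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    lineages = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a)
        a.edge.length = float(rng.uniform(bl_low, bl_high))
        parent.add_child(b)
        b.edge.length = float(rng.uniform(bl_low, bl_high))
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=lineages[0])
    tree.is_rooted = False
    return tree
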