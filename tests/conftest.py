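"""Shared fixtures and generators for the test suite.

All fixtures are generated programmatically; no data files are read.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathphylo.graph import PathwayGraph


def make_graph(species, edges, n_nodes=None, members=None):
    """Compact PathwayGraph builder: integer nodes, auto member ids."""
    node_ids = sorted({u for e in edges for u in e} | set(range(n_nodes or 0)))
    if not node_ids and n_nodes:
        node_ids = list(range(n_nodes))
    nodes = [
        (i, [members[i]] if members else [f"m{i:03d}"], "gene") for i in node_ids
    ]
    return PathwayGraph.build(species, nodes, edges)


def random_pathway_graph(n, p, seed, species="syn"):
    """Erdos-Renyi pathway graph with deterministic member ids."""
    rng = np.random.default_rng(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return make_graph(species, edges, n_nodes=n)


@pytest.fixture
def triangle():
    return make_graph("tri", [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return make_graph("p3", [(0, 1), (1, 2)])


@pytest.fixture
def star4():
    return make_graph("st", [(0, i) for i in range(1, 5)])
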