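"""Topological tree comparison by optimal one-to-one branch matching.

Two unrooted trees on the same leaf set are compared by scoring every
pair of branches — each branch is identified with the bipartition
(split) of the leaf set it induces — and finding the bijection between
branch sets that maximizes the total score.  The per-pair score is the
max-of-min Jaccard pairing of split sides: for splits P = A|B and
Q = C|D,

    s(P, Q) = max( min(J(A,C), J(B,D)), min(J(A,D), J(B,C)) ),

which is 1 exactly when the splits are identical.  The optimum
bijection is found exactly by an optimal-assignment solve on the full
score grid; when branch counts differ the smaller set is padded with
null partners scoring 0.  The summary percentage divides the total by
the larger branch count (pendant and internal branches alike; an
internal-only variant is available).  Branch lengths are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .trees import leaf_labels


@dataclass(frozen=True)
class Bipartition:
    """The two complementary leaf-label sets induced by one branch.

    ``side_a`` always contains the lexicographically smallest leaf (the
    other side is listed second).
    """

    side_a: frozenset[str]
    side_b: frozenset[str]
    branch_id: int

    @property
    def is_pendant(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    @property
    def leaf_set(self) -> frozenset[str]:
        return self.side_a | self.side_b


@dataclass(frozen=True)
class BranchMatching:
    """Optimal bijection between two trees' branches with per-pair scores."""

    pairs: tuple[tuple[Bipartition, Bipartition, float], ...]
    unmatched_t1: tuple[Bipartition, ...]
    unmatched_t2: tuple[Bipartition, ...]
    total: float
    n_branches_t1: int
    n_branches_t2: int


def bipartitions(tree: dendropy.Tree) -> list[Bipartition]:
    """One bipartition per branch (pendant branches yield singleton sides).

    The degree-2 root of a rooted representation would induce one split
    twice; duplicates are collapsed so the list matches the unrooted
    branch set.
    """
    leaves = leaf_labels(tree)
    if len(leaves) < 2:
        raise ValidationError("bipartitions need a tree with at least 2 leaves")
    smallest = min(leaves)
    seen: dict[frozenset[str], Bipartition] = {}
    order: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(
            l.taxon.label for l in node.leaf_iter() if l.taxon is not None
        )
        if not below or below == leaves:
            continue
        side_a, side_b = (
            (below, leaves - below) if smallest in below else (leaves - below, below)
        )
        if side_a not in seen:
            seen[side_a] = Bipartition(side_a, side_b, len(seen))
            order.append(side_a)
    return [seen[k] for k in order]


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def branch_score(p: Bipartition, q: Bipartition) -> float:
    """Max-of-min Jaccard score of two splits over the same leaf set."""
    if p.leaf_set != q.leaf_set:
        diff = sorted(p.leaf_set ^ q.leaf_set)
        raise ValidationError(
            f"bipartitions over different leaf sets; symmetric difference: {diff}"
        )
    straight = min(_jaccard(p.side_a, q.side_a), _jaccard(p.side_b, q.side_b))
    crossed = min(_jaccard(p.side_a, q.side_b), _jaccard(p.side_b, q.side_a))
    return max(straight, crossed)


def score_grid(bips1, bips2) -> np.ndarray:
    return np.array([[branch_score(p, q) for q in bips2] for p in bips1])


def optimal_branch_map(
    t1: dendropy.Tree, t2: dendropy.Tree, internal_only: bool = False
) -> BranchMatching:
    """Exact maximum-score bijection between the two trees' branch sets.

    Solved as an optimal assignment on the full score grid, padded with
    zero-score null partners when branch counts differ (e.g. against
    non-binary taxonomy trees).
    """
    if leaf_labels(t1) != leaf_labels(t2):
        diff = sorted(leaf_labels(t1) ^ leaf_labels(t2))
        raise ValidationError(f"trees have different leaf sets: {diff}")
    bips1, bips2 = bipartitions(t1), bipartitions(t2)
    if internal_only:
        bips1 = [b for b in bips1 if not b.is_pendant]
        bips2 = [b for b in bips2 if not b.is_pendant]
    n1, n2 = len(bips1), len(bips2)
    size = max(n1, n2)
    grid = np.zeros((size, size))
    if n1 and n2:
        grid[:n1, :n2] = score_grid(bips1, bips2)
    rows, cols = linear_sum_assignment(grid, maximize=True)
    pairs = []
    matched1, matched2 = set(), set()
    for i, j in zip(rows, cols):
        if i < n1 and j < n2:
            pairs.append((bips1[i], bips2[j], float(grid[i, j])))
            matched1.add(i)
            matched2.add(j)
    total = float(sum(s for _, _, s in pairs))
    return BranchMatching(
        pairs=tuple(pairs),
        unmatched_t1=tuple(b for i, b in enumerate(bips1) if i not in matched1),
        unmatched_t2=tuple(b for j, b in enumerate(bips2) if j not in matched2),
        total=total,
        n_branches_t1=n1,
        n_branches_t2=n2,
    )


def similarity_percent(match: BranchMatching) -> float:
    """100 x total score / max branch count."""
    denom = max(match.n_branches_t1, match.n_branches_t2)
    if denom == 0:
        return 100.0
    return 100.0 * match.total / denom


def compare_trees(
    t1: dendropy.Tree, t2: dendropy.Tree, internal_only: bool = False
) -> tuple[BranchMatching, float]:
    match = optimal_branch_map(t1, t2, internal_only=internal_only)
    return match, similarity_percent(match)


def _nontrivial_splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    return frozenset(
        b.side_a for b in bipartitions(tree) if not b.is_pendant
    )


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: symmetric difference of nontrivial splits."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValidationError("trees have different leaf sets")
    return len(_nontrivial_splits(t1) ^ _nontrivial_splits(t2))
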