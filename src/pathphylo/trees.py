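"""Tree construction: Neighbor-Joining, sequence distances, Newick I/O.

Trees are :class:`dendropy.Tree` objects throughout the package
(unrooted; leaf taxa labeled with species codes).  Neighbor-Joining is
implemented here rather than delegated so that its tie-breaking
(smallest label pair) and its treatment of negative branch lengths are
part of the documented contract; dendropy's own NJ serves as an
independent cross-check in the test suite.

For the ribosomal-RNA reference workflow the package computes
p-distances and Jukes-Cantor distances from a FASTA alignment with
either pairwise or complete deletion of gap/missing sites.  Externally
computed distance matrices (e.g. Maximum Composite Likelihood from
other software) can be supplied as TSV instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO

from .distance import SpeciesDistanceMatrix
from .errors import ParseError, ValidationError

MISSING_CHARS = frozenset("-?Nn")


# -- Neighbor-Joining ------------------------------------------------


def neighbor_joining(
    dm: SpeciesDistanceMatrix, clamp_negative: bool = False
) -> dendropy.Tree:
    """Classic agglomerative Neighbor-Joining.

    Q-matrix pair selection with standard branch-length and
    distance-update formulas; ties are broken by the smallest sorted
    label pair of the clusters involved.  Negative branch lengths are
    kept as computed unless ``clamp_negative`` is set, in which case
    the negative amount is moved onto the sister branch.

    With two taxa the result is a single branch of the given length
    (split evenly across the rooted representation).
    """
    n = len(dm.species)
    if n < 2:
        raise ValidationError("neighbor joining needs at least 2 taxa")

    taxa = dendropy.TaxonNamespace(list(dm.species))
    nodes: dict[str, dendropy.Node] = {}
    dist: dict[frozenset[str], float] = {}
    # cluster key: the smallest leaf label it contains (deterministic)
    for i, sp in enumerate(dm.species):
        leaf = dendropy.Node(taxon=taxa.get_taxon(sp))
        nodes[sp] = leaf
        for j in range(i + 1, n):
            dist[frozenset((sp, dm.species[j]))] = float(dm.values[i, j])

    active = sorted(nodes)

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[frozenset((a, b))]

    def attach(parent: dendropy.Node, child_key: str, length: float) -> None:
        parent.add_child(nodes[child_key])
        nodes[child_key].edge.length = length

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if clamp_negative:
            la, lb = _clamp_pair(la, lb)
        new_key = min(a, b)
        parent = dendropy.Node()
        updates = {k: (d(a, k) + d(b, k) - dab) / 2 for k in active if k not in (a, b)}
        attach(parent, a, la)
        attach(parent, b, lb)
        nodes[new_key] = parent
        active = sorted(set(active) - {a, b} | {new_key})
        for k, v in updates.items():
            dist[frozenset((new_key, k))] = v

    if len(active) == 3:
        a, b, c = active
        la = (d(a, b) + d(a, c) - d(b, c)) / 2
        lb = (d(a, b) + d(b, c) - d(a, c)) / 2
        lc = (d(a, c) + d(b, c) - d(a, b)) / 2
        center = dendropy.Node()
        attach(center, a, la)
        attach(center, b, lb)
        attach(center, c, lc)
        root = center
    else:  # exactly two clusters remain
        a, b = active
        dab = d(a, b)
        root = dendropy.Node()
        attach(root, a, dab / 2)
        attach(root, b, dab / 2)

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return la, max(lb, 0.0)


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges() if e.head_node is not tree.seed_node)


def patristic_distance_matrix(tree: dendropy.Tree) -> SpeciesDistanceMatrix:
    """Leaf-to-leaf path-length (additive) distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return SpeciesDistanceMatrix(tuple(labels), values, "patristic")


# -- aligned sequences and sequence distances ------------------------


@dataclass(frozen=True)
class AlignedSequences:
    """Equal-length sequences over {A, C, G, T, U, N, -, ?} per species."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValidationError("alignment needs at least 2 sequences")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate sequence names in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )

    @classmethod
    def from_fasta(cls, path) -> "AlignedSequences":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ParseError(f"no sequences found in {path}")
        return cls(
            tuple(r.id for r in records), tuple(str(r.seq).upper() for r in records)
        )


def _normalize(base: str) -> str:
    b = base.upper()
    return "T" if b == "U" else b


def _comparable(a: str, b: str) -> bool:
    return a not in MISSING_CHARS and b not in MISSING_CHARS


def pairwise_p_distance(
    aln: AlignedSequences, deletion: str = "pairwise", return_counts: bool = False
):
    """Proportion of differing sites per species pair.

    ``pairwise`` deletion excludes gap/missing sites per pair;
    ``complete`` uses only columns clean in every sequence.  U is
    treated as T; N and ? are treated as missing.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValidationError(f"unknown deletion mode {deletion!r}")
    seqs = [[_normalize(ch) for ch in s] for s in aln.sequences]
    length = len(seqs[0])
    if deletion == "complete":
        clean = [
            k for k in range(length) if all(s[k] not in MISSING_CHARS for s in seqs)
        ]
        seqs = [[s[k] for k in clean] for s in seqs]
        length = len(clean)
    n = len(seqs)
    values = np.zeros((n, n))
    counts: dict[tuple[str, str], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [
                (a, b) for a, b in zip(seqs[i], seqs[j]) if _comparable(a, b)
            ]
            if not pairs:
                raise ValidationError(
                    f"zero comparable sites for pair ({aln.names[i]}, {aln.names[j]})"
                )
            diff = sum(1 for a, b in pairs if a != b)
            values[i, j] = values[j, i] = diff / len(pairs)
            counts[aln.names[i], aln.names[j]] = len(pairs)
    dm = SpeciesDistanceMatrix(aln.names, values, "sequence")
    return (dm, counts) if return_counts else dm


def jukes_cantor_distance(
    aln: AlignedSequences, deletion: str = "pairwise"
) -> SpeciesDistanceMatrix:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) of the p-distance."""
    p = pairwise_p_distance(aln, deletion)
    n = len(p.species)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pij = p.values[i, j]
            if pij >= 0.75:
                raise ValidationError(
                    f"Jukes-Cantor distance undefined for pair "
                    f"({p.species[i]}, {p.species[j]}): p = {pij:.4f} >= 0.75"
                )
            values[i, j] = values[j, i] = -0.75 * math.log(1.0 - 4.0 * pij / 3.0)
    return SpeciesDistanceMatrix(p.species, values, "sequence")


# -- Newick I/O ------------------------------------------------------


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize to Newick (10+ significant digits on branch lengths)."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_newick(source) -> dendropy.Tree:
    """Parse Newick text or a file path into an unrooted tree."""
    if isinstance(source, str) and "(" in source:
        text = source
    else:  # a path
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise ParseError(f"cannot parse Newick: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf labels: {', '.join(dupes)}")
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(
        l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None
    )
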