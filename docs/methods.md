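# Methods

## Pathway graphs

A pathway is modeled as an undirected simple graph per species. KGML
relations are directional and may repeat between the same entry pair;
both properties are dropped at parse time because every downstream
computation uses either node membership (module distances) or simple
undirected topology (graphlet counting), and "total degree" is then
simply the number of distinct neighbours. Node identity is local to a
graph; cross-species identity lives only in the member identifiers
attached to each node.

KGML handling: gene-like entries (`gene`, `ortholog`, `enzyme`) always
become nodes; `compound` entries only with `include_compounds` (off by
default — membership comparison is about gene content); `map` entries
and `maplink` relations are dropped. Group entries (complexes) are
expanded to their members with a clique among them, and relations
touching a group re-attach to every member: membership-based similarity
needs genes, not complex placeholders. The cross-species member
namespace is deliberately explicit: by default the KGML name tokens
with the database prefix stripped, or a user-supplied two-column table
(e.g. KEGG Orthology). Nothing in a KGML file fixes this choice, so it
is surfaced as an option and recorded in every run manifest.

## Modularization

A module is a connected subgraph that keeps most of its edges internal.
The decomposition is degree-seeded synchronous label propagation with a
user factor *c* (legal range 1 … max total degree, checked at call
time):

1. every node of total degree ≥ *c* opens its own module;
2. synchronous rounds: each unassigned node adjacent to at least one
   module joins the module to which it has most edges — ties broken by
   the module containing its highest-degree assigned neighbour, then by
   the module with the smallest member identifier;
3. seedless connected components become whole modules; isolated nodes
   become singletons.

The output is a partition (modules are disjoint and cover the graph,
each inducing a connected subgraph), deterministic and independent of
node iteration order because each round only reads the previous round's
assignment. Module count is non-increasing in *c*: per component the
count is its seed count while seeds exist, then 1. Overlapping modules
are excluded by construction since the grid normalization of the
species similarity presupposes a fixed module list. The algorithm sits
behind a single entry point taking a config object, so alternative
modularization policies can be added without touching the distances.
Default *c* = 3, mid-range for pathway graphs whose maximum degrees run
roughly 5–10; always recorded in the run manifest.

## Module distances

Module similarity is the Jaccard index of the two modules' member-id
sets (node ids are meaningless across species). Species similarity
averages over **all** m₁ × m₂ module pairs — including obviously
unrelated pairs; no best-match variant is substituted — and the
distance is its complement. The sum is accumulated in exact rational
arithmetic so that S_M(x, y) = S_M(y, x) holds to the last bit.

One consequence deserves emphasis: S_M(x, x) < 1 whenever a species has
two or more non-identical modules (the off-diagonal grid terms are not
1), so the self-distance under the defining equations is positive. The
distance matrix forces its diagonal to zero — tree construction
consumes off-diagonals only — and logs the raw self-value.

## Graphlet signatures and alignment

The pathway-topology distance follows the graphlet-signature,
seed-and-extend family of global network aligners. There are 30
connected graphs on 2–5 nodes and their nodes occupy 73 automorphism
orbits; a node's signature counts its occurrences in each orbit over
all connected induced subgraphs (orbit 0 is the degree). The atlas of
graphlets and orbits is generated at import time from first principles
— enumeration, canonicalization, automorphism orbits — and ordered
deterministically (node count, edge count, descending degree sequence,
canonical form; orbits within a graphlet by degree, neighbour degrees,
triangle count, distance profile). For graphlets up to 4 nodes this
ordering reproduces the standard published orbit numbering 0–14; the
5-node orbits follow the same rule, which is internally consistent but
has not been collated position by position against the published
5-node chart — nothing downstream depends on the labels, only on the
partition they induce.

Signature similarity uses logarithmic per-orbit distances weighted by
w_i = 1 − log(o_i)/log 73, where o_i counts the orbits that affect
orbit i. The dependency counts are computed from the atlas (the number
of distinct orbits the representative node touches across connected
induced subgraphs of the orbit's own graphlet) rather than transcribed
from a table; the computed values reproduce the hand-derivable counts
for all 2–4-node orbits (1, 2, 2, 2, 3, 4, 3, 3, 4, 3, 4, 4, 4, 4, 3).

Alignment embeds the smaller graph into the larger: node-pair cost
blends normalized degrees with signature similarity through α (default
0.8, exposed as a flag; the balance between topology-local and
signature information), the seed is the cheapest pair, and extension
matches breadth-first spheres of equal radius (radii 1–3) around
already-aligned pairs, cheapest pair first. Components of a
disconnected smaller graph are processed in decreasing size; leftovers
are matched greedily by cost. Ties break by (cost, degree gap,
lexicographic pair) everywhere, so the aligner is deterministic;
optional random restarts keep the best edge correctness. Edge
correctness of an edgeless graph is 1 by convention (logged): the
distance must be total, and a zero-edge graph preserves all of its
edges vacuously. The distance wrapper orders arguments canonically
(node count, edge count, species code) so D_P is symmetric. The greedy
aligner is a heuristic: self-alignment of a connected 15-node graph at
density 0.25 typically attains edge correctness near 1, but optimality
is not guaranteed and not asserted.

## Trees

Neighbor-Joining is implemented with the classic Q-matrix selection and
branch-length/update formulas, with ties broken by the smallest sorted
label pair, making the output unique. On additive inputs it recovers
the generating topology and branch lengths to numerical precision
(verified against dendropy's independent implementation). Negative
branch lengths are kept as computed by default — preserving the
algorithm's algebra — with `--clamp-negative` moving the negative
amount onto the sister branch for viewers that require non-negative
lengths.

Sequence distances for the reference-tree workflow: p-distance and its
Jukes–Cantor correction −(3/4)·ln(1 − 4p/3), with pairwise deletion
(gap/missing sites excluded per pair; U≡T, N and ? treated as missing)
or complete deletion (globally clean columns only). Pairs at p ≥ 0.75
have no defined Jukes–Cantor distance and raise an error naming the
pair. Model-based substitution distances from other software can be
supplied as a TSV matrix instead; the tree builder does not care where
the matrix came from.

## Tree comparison

Each branch of an unrooted tree induces a bipartition of the leaf set;
pendant branches count. A pair of splits scores
max(min(J(A,C), J(B,D)), min(J(A,D), J(B,C))) for sides A|B vs C|D —
1 exactly for identical splits. The optimal bijection between branch
sets is found exactly by a linear assignment solve on the full score
grid, padding the smaller branch set with zero-score null partners when
counts differ (non-binary taxonomies). The summary percentage divides
the total by the **larger** branch count over all branches, pendant and
internal; `--internal-only` restricts both sets to internal branches
for users who consider pendant matches trivial. Branch lengths are
ignored throughout. Robinson–Foulds distance (symmetric difference of
nontrivial splits) is provided for evaluation.

## Synthetic pathway families

The generator evolves an ancestral Erdős–Rényi connected graph
(regenerated until connected) along a planted phylogeny. Per branch of
length t, Poisson(rate·t) events: node losses (uniform victim; node and
incident edges removed), node gains (a fresh member attached to 1–3
existing nodes, chosen with probability proportional to degree + 1 so
hubs persist and modularization has structure), and optional edge
rewires. Member identifiers come from one global namespace, so
cross-species module intersections are exact by construction. Defaults:
ancestor 40 nodes at edge density 0.15, loss = gain = 0.08 events per
unit branch length, rewires off.

The default planted tree has a uniformly random join topology with
internal branches of 60 time units and pendant branches of 20. The
asymmetry is deliberate: internal branches carry the recoverable
topological signal (≈4.8 expected gains+losses each, so the chance an
internal branch leaves no trace is below 1 %), while events on pendant
branches are phylogenetically uninformative noise, so pendants are kept
short — the regime of a densely sampled clade. Design-phase pilots at
80 replicates in this regime put module-tree topology recovery around
90–95 % with mean Robinson–Foulds distance ≈ 0.1, statistically
indistinguishable from a whole-pathway-Jaccard control. Deep
ultrametric profiles were rejected: long pendants add noise without
signal, and at 0.08 events/unit a root-to-leaf path much beyond ~300
units loses more nodes than the 40-node ancestor has.

What the generator does not emulate: curation-effort bias between
well- and poorly-studied organisms, non-uniform (hub-avoiding or
hub-seeking) loss, correlated gain/loss of complex members, orthology-
mapping noise, and realistic pathway degree distributions. Passing
tests therefore demonstrate correctness and recoverability under clean
gain/loss evolution with exact orthology — not performance on real
database content, where the member-matching rule dominates.

## Numerical and interface choices

- Distance matrices are validated on construction: symmetric, zero
  diagonal, no NaN; module and pathway-topology distances must lie in
  [0, 1] (corrected sequence distances are unbounded above).
- Text outputs print 10 significant digits; JSON reports carry full
  doubles. Newick round-trips are exact to 1e-10.
- Every CLI invocation writes one JSON manifest (command, argv,
  parameter values, SHA-256 input digests, package version, timestamp).
  Primary outputs contain no timestamps, so `rerun` reproduces them
  byte for byte.
- Problem sizes in the test suite and acceptance script (graphs of
  12–40 nodes, 20 simulated families, 25–50 random trees) are chosen to
  exercise every code path at desk scale; all scale linearly upward via
  the same entry points.

## Known limitations

- The modularization is one concrete policy satisfying the qualitative
  constraints (user factor, degree-bounded range, granularity that
  tracks size and complexity); other decompositions meeting the same
  constraints would yield different module counts and distances.
- The greedy aligner under-estimates edge correctness on graphs with
  many automorphisms or near-symmetries; restarts mitigate but do not
  eliminate this.
- The grid-averaged species similarity compresses toward 0 as module
  counts grow (the diagonal of the grid carries a 1/(m₁m₂) weight), so
  distances between fine-grained decompositions cluster near 1 and the
  informative dynamic range is small; this is a property of the
  defining equations, not of the implementation.
- p-distance/Jukes–Cantor are simple stand-ins for model-based
  substitution distances; no alignment step is provided.
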