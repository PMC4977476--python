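"""Module-overlap distances between species.

Given the module decompositions of two species' pathways, the
similarity of a module pair is the Jaccard index of their member sets,

    Sim(M1, M2) = |M1 ∩ M2| / |M1 ∪ M2|,

the species similarity is the mean of Sim over the full m1 x m2 module
grid,

    S_M(x, y) = sum_{i,j} Sim(Mi, Mj) / (m1 * m2),

and the species distance is D_M(x, y) = 1 - S_M(x, y).  All module
pairs contribute, not only best matches.  Note that S_M(x, x) < 1
whenever a species has more than one (non-identical) module; the
distance-matrix diagonal is therefore forced to zero explicitly, which
is what tree construction consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .modularize import ModuleSet

logger = logging.getLogger(__name__)


@dataclass
class SpeciesDistanceMatrix:
    """Symmetric zero-diagonal distance matrix over an ordered species list.

    ``provenance`` records which pipeline produced it: ``module``,
    ``pathway-topology`` or ``sequence``.  Module and pathway distances
    are bounded in [0, 1]; sequence distances may exceed 1 (corrected
    substitution distances are unbounded above).
    """

    species: tuple[str, ...]
    values: np.ndarray
    provenance: str = "module"

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} species"
            )
        if len(set(self.species)) != n:
            raise ValidationError("duplicate species codes in distance matrix")
        if np.any(np.isnan(self.values)):
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.any(self.values < 0.0):
            raise ValidationError("negative distances")
        if self.provenance in ("module", "pathway-topology") and np.any(
            self.values > 1.0 + 1e-12
        ):
            raise ValidationError(
                f"{self.provenance} distances must lie in [0, 1]"
            )

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.species.index(pair[0]), self.species.index(pair[1])
        return float(self.values[i, j])


def module_similarity(m1: frozenset, m2: frozenset) -> float:
    """Jaccard similarity of two module member sets."""
    if not m1 or not m2:
        raise ValidationError("module similarity undefined for empty modules")
    inter = len(m1 & m2)
    union = len(m1 | m2)
    return float(Fraction(inter, union))


def species_similarity(mset_x: ModuleSet, mset_y: ModuleSet) -> float:
    """Mean module similarity over all m1 x m2 module pairs."""
    if len(mset_x) == 0:
        raise ValidationError(f"species {mset_x.species_code!r} has no modules")
    if len(mset_y) == 0:
        raise ValidationError(f"species {mset_y.species_code!r} has no modules")
    # exact rational accumulation keeps S_M(x, y) == S_M(y, x) to the bit
    total = Fraction(0)
    for mx in mset_x.member_view:
        for my in mset_y.member_view:
            if not mx or not my:
                raise ValidationError("module similarity undefined for empty modules")
            total += Fraction(len(mx & my), len(mx | my))
    return float(total / (len(mset_x) * len(mset_y)))


def species_distance(mset_x: ModuleSet, mset_y: ModuleSet) -> float:
    """Distance D_M = 1 - S_M between two species' module sets."""
    return 1.0 - species_similarity(mset_x, mset_y)


def module_pair_similarity_matrix(mset_x: ModuleSet, mset_y: ModuleSet) -> np.ndarray:
    """The m1 x m2 grid of module-pair similarities."""
    return np.array(
        [
            [module_similarity(mx, my) for my in mset_y.member_view]
            for mx in mset_x.member_view
        ]
    )


def build_distance_matrix(
    msets: Sequence[ModuleSet], provenance: str = "module"
) -> SpeciesDistanceMatrix:
    """All-pairs species distance matrix with the diagonal forced to 0.

    The raw self-similarity S_M(x, x) is generally below 1, so the raw
    self-distance is logged and replaced by the 0 the tree builder
    requires.
    """
    codes = [m.species_code for m in msets]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValidationError(f"duplicate species codes: {', '.join(dupes)}")
    if len(msets) < 2:
        raise ValidationError("need at least 2 species")
    n = len(msets)
    values = np.zeros((n, n))
    for i in range(n):
        raw_self = species_distance(msets[i], msets[i])
        if raw_self != 0.0:
            logger.debug(
                "raw self-distance of %s is %.6f; diagonal forced to 0",
                codes[i],
                raw_self,
            )
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = species_distance(msets[i], msets[j])
    return SpeciesDistanceMatrix(tuple(codes), values, provenance)


# -- matrix I/O ------------------------------------------------------


def write_distance_tsv(dm: SpeciesDistanceMatrix, path) -> None:
    """Square TSV with a header row/column of species codes."""
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(dm.species) + "\n")
        for i, sp in enumerate(dm.species):
            row = "\t".join(f"{v:.10g}" for v in dm.values[i])
            fh.write(f"{sp}\t{row}\n")


def read_distance_tsv(path, provenance: str = "module") -> SpeciesDistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "species":
            raise ValidationError(f"bad distance matrix header in {path}")
        species = tuple(header[1:])
        rows = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return SpeciesDistanceMatrix(species, np.array(rows), provenance)


def write_phylip(dm: SpeciesDistanceMatrix, path) -> None:
    """Lower-triangular PHYLIP-style matrix for interoperability."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.species)}\n")
        for i, sp in enumerate(dm.species):
            cells = " ".join(f"{dm.values[i, j]:.10g}" for j in range(i))
            fh.write(f"{sp:<10s} {cells}".rstrip() + "\n")
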