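import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathphylo.distance import (
    SpeciesDistanceMatrix,
    build_distance_matrix,
    module_similarity,
    read_distance_tsv,
    species_distance,
    species_similarity,
    write_distance_tsv,
    write_phylip,
)
from pathphylo.errors import ValidationError
from pathphylo.modularize import ModuleSet


def mset(code, *member_sets):
    return ModuleSet(
        code,
        tuple(frozenset({f"n{code}{i}"}) for i in range(len(member_sets))),
        tuple(frozenset(m) for m in member_sets),
    )


class TestModuleSimilarity:
    def test_half_overlap(self):
        assert module_similarity(frozenset("abc"), frozenset("bcd")) == 0.5

    def test_identity(self):
        assert module_similarity(frozenset("ab"), frozenset("ab")) == 1.0

    def test_disjoint(self):
        assert module_similarity(frozenset("ab"), frozenset("cd")) == 0.0

    def test_empty_module_rejected(self):
        with pytest.raises(ValidationError):
            module_similarity(frozenset(), frozenset("a"))


class TestSpeciesSimilarity:
    def test_identical_single_modules(self):
        assert species_similarity(mset("x", "ab"), mset("y", "ab")) == 1.0

    def test_two_by_one_grid(self):
        x = mset("x", "ab", "cd")
        y = mset("y", "ab")
        assert species_similarity(x, y) == 0.5
        assert species_distance(x, y) == 0.5

    def test_self_similarity_below_one_with_disjoint_modules(self):
        x = mset("x", "a", "b")
        # grid (1+0+0+1)/4
        assert species_similarity(x, x) == 0.5

    def test_symmetry(self):
        x, y = mset("x", "ab", "cde"), mset("y", "bc", "e", "f")
        assert species_similarity(x, y) == species_similarity(y, x)

    def test_empty_module_set_rejected(self):
        with pytest.raises(ValidationError, match="x"):
            species_similarity(ModuleSet("x", (), ()), mset("y", "ab"))


class TestBuildDistanceMatrix:
    def test_identical_species_zero_matrix(self):
        ms = [mset(c, "ab") for c in "xyz"]
        dm = build_distance_matrix(ms)
        assert np.all(dm.values == 0.0)

    def test_worked_placement(self):
        x = mset("x", "ab", "cd")
        y = mset("y", "ab")
        x2 = mset("z", "ab", "cd")
        dm = build_distance_matrix([x, y, x2])
        assert dm["x", "y"] == 0.5 and dm["y", "x"] == 0.5
        # z is a copy of x, but two disjoint modules average to 0.5 even
        # between identical species; only the diagonal is forced to 0
        assert dm["x", "z"] == 0.5
        assert set(np.unique(dm.values)) == {0.0, 0.5}
        assert np.all(np.diag(dm.values) == 0.0)

    def test_permutation_equivariance(self):
        ms = [mset("a", "pq"), mset("b", "qr", "s"), mset("c", "p")]
        dm1 = build_distance_matrix(ms)
        dm2 = build_distance_matrix(ms[::-1])
        for s1 in "abc":
            for s2 in "abc":
                assert dm1[s1, s2] == dm2[s1, s2]

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValidationError, match="x"):
            build_distance_matrix([mset("x", "a"), mset("x", "b")])


@st.composite
def random_module_sets(draw):
    alphabet = [f"K{i:02d}" for i in range(12)]
    n_mod = draw(st.integers(1, 4))
    members = [
        draw(st.sets(st.sampled_from(alphabet), min_size=1, max_size=5))
        for _ in range(n_mod)
    ]
    return members


class TestProperties:
    @settings(max_examples=60, derandomize=True)
    @given(random_module_sets(), random_module_sets())
    def test_similarity_bounds_and_symmetry(self, ma, mb):
        x = mset("x", *ma)
        y = mset("y", *mb)
        s = species_similarity(x, y)
        assert 0.0 <= s <= 1.0
        assert s == species_similarity(y, x)
        assert species_distance(x, y) == 1.0 - s

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_evaluator(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = [f"K{i:02d}" for i in range(15)]
        msets = []
        for k in range(4):
            mods = [
                frozenset(rng.choice(alphabet, size=rng.integers(1, 5), replace=False))
                for _ in range(rng.integers(1, 5))
            ]
            msets.append(
                ModuleSet(
                    f"s{k}",
                    tuple(frozenset({i}) for i in range(len(mods))),
                    tuple(mods),
                )
            )
        dm = build_distance_matrix(msets)
        # independent double-loop evaluation of the defining equations
        for i, x in enumerate(msets):
            for j, y in enumerate(msets):
                if i == j:
                    continue
                total = 0.0
                for mx in x.member_view:
                    for my in y.member_view:
                        total += len(mx & my) / len(mx | my)
                expected = 1.0 - total / (len(x.member_view) * len(y.member_view))
                assert abs(dm.values[i, j] - expected) < 1e-12


class TestMatrixContainer:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            SpeciesDistanceMatrix(("a", "b"), np.array([[0, 0.1], [0.2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValidationError):
            SpeciesDistanceMatrix(("a", "b"), np.array([[0.1, 0.2], [0.2, 0]]))

    def test_tsv_round_trip(self, tmp_path):
        dm = build_distance_matrix([mset("a", "pq"), mset("b", "qr"), mset("c", "p")])
        write_distance_tsv(dm, tmp_path / "d.tsv")
        dm2 = read_distance_tsv(tmp_path / "d.tsv")
        assert dm2.species == dm.species
        assert np.allclose(dm2.values, dm.values)

    def test_phylip_writer(self, tmp_path):
        dm = build_distance_matrix([mset("a", "pq"), mset("b", "qr"), mset("c", "p")])
        write_phylip(dm, tmp_path / "d.phy")
        lines = (tmp_path / "d.phy").read_text().splitlines()
        assert lines[0] == "3"
        assert len(lines) == 4
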