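import dendropy
import numpy as np
import pytest

from pathphylo.distance import SpeciesDistanceMatrix
from pathphylo.errors import ParseError, ValidationError
from pathphylo.treecompare import rf_distance
from pathphylo.trees import (
    AlignedSequences,
    jukes_cantor_distance,
    neighbor_joining,
    pairwise_p_distance,
    parse_newick,
    patristic_distance_matrix,
    total_branch_length,
    write_newick,
)

from oracles import random_binary_tree


def dm_from(labels, matrix, provenance="patristic"):
    return SpeciesDistanceMatrix(tuple(labels), np.array(matrix, float), provenance)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = dm_from("ABC", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = neighbor_joining(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_two_taxa_single_branch(self):
        dm = dm_from("AB", [[0, 0.5], [0.5, 0]])
        tree = neighbor_joining(dm)
        assert total_branch_length(tree) == pytest.approx(0.5)

    def test_additive_four_taxon_exact_recovery(self):
        planted = parse_newick("((A:1,B:2):1,(C:3,D:4):0);")
        dm = patristic_distance_matrix(planted)
        tree = neighbor_joining(dm)
        assert rf_distance(planted, tree) == 0
        back = patristic_distance_matrix(tree)
        assert np.allclose(back.values, dm.values, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_consistency_on_additive_inputs(self, seed):
        rng = np.random.default_rng(seed)
        planted = random_binary_tree(int(rng.integers(5, 12)), seed)
        dm = patristic_distance_matrix(planted)
        tree = neighbor_joining(dm)
        assert rf_distance(planted, tree) == 0
        assert np.allclose(
            patristic_distance_matrix(tree).values, dm.values, atol=1e-9
        )

    def test_agrees_with_dendropy_nj_on_additive_input(self):
        planted = random_binary_tree(9, 123)
        dm = patristic_distance_matrix(planted)
        mine = neighbor_joining(dm)
        # independent route: dendropy's NJ from a PHYLIP-style CSV
        src = ",".join([""] + list(dm.species)) + "\n"
        for i, sp in enumerate(dm.species):
            src += ",".join([sp] + [repr(float(v)) for v in dm.values[i]]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=[line + "\n" for line in src.splitlines()], delimiter=","
        )
        theirs = pdm.nj_tree()
        theirs.is_rooted = False
        assert rf_distance(mine, theirs) == 0

    def test_leaf_permutation_equivariance(self):
        planted = random_binary_tree(7, 5)
        dm = patristic_distance_matrix(planted)
        perm = [3, 1, 4, 0, 6, 2, 5]
        labels = [dm.species[i] for i in perm]
        values = dm.values[np.ix_(perm, perm)]
        tree1 = neighbor_joining(dm)
        tree2 = neighbor_joining(dm_from(labels, values))
        assert rf_distance(tree1, tree2) == 0

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            dm_from("AB", [[0, np.nan], [np.nan, 0]])

    def test_negative_lengths_kept_unless_clamped(self):
        dm = dm_from(
            "ABCD",
            [
                [0, 0.1, 0.4, 0.5],
                [0.1, 0, 0.45, 0.55],
                [0.4, 0.45, 0, 0.05],
                [0.5, 0.55, 0.05, 0],
            ],
        )
        raw = neighbor_joining(dm)
        clamped = neighbor_joining(dm, clamp_negative=True)
        assert min(e.length for e in raw.edges() if e.length is not None) < 0
        assert min(e.length for e in clamped.edges() if e.length is not None) >= 0


class TestSequenceDistances:
    def aln(self, **seqs):
        return AlignedSequences(tuple(seqs), tuple(seqs.values()))

    def test_p_distance_simple(self):
        dm, counts = pairwise_p_distance(
            self.aln(a="ACGT", b="ACGA"), return_counts=True
        )
        assert dm["a", "b"] == 0.25
        assert counts["a", "b"] == 4

    def test_pairwise_deletion_skips_gaps(self):
        dm, counts = pairwise_p_distance(
            self.aln(a="AC-T", b="ACGT"), return_counts=True
        )
        assert dm["a", "b"] == 0.0
        assert counts["a", "b"] == 3

    def test_complete_deletion_uses_clean_columns_only(self):
        aln = self.aln(a="AC-T", b="ACGT", c="GCGT")
        dm = pairwise_p_distance(aln, deletion="complete")
        # columns 0,1,3 are clean; a vs b differ nowhere there
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == pytest.approx(1 / 3)

    def test_u_equals_t_and_missing_symbols(self):
        dm = pairwise_p_distance(self.aln(a="ACGU", b="ACGT"))
        assert dm["a", "b"] == 0.0
        dm2 = pairwise_p_distance(self.aln(a="ACNT", b="AC?T"))
        assert dm2["a", "b"] == 0.0

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValidationError, match="a.*b"):
            pairwise_p_distance(self.aln(a="--AA", b="GG--"))

    def test_jukes_cantor_values(self):
        dm = jukes_cantor_distance(self.aln(a="AAAA", b="AAAA"))
        assert dm["a", "b"] == 0.0
        dm2 = jukes_cantor_distance(self.aln(a="ACGT", b="ACGA"))
        assert dm2["a", "b"] == pytest.approx(0.30409883108112214)

    def test_jukes_cantor_saturated_pair_raises(self):
        with pytest.raises(ValidationError, match="0.75"):
            jukes_cantor_distance(self.aln(a="ACGTA", b="CGTAC"))

    def test_jc_geq_p(self):
        aln = self.aln(a="ACGTACGTAC", b="ACGAACGTGC")
        p = pairwise_p_distance(aln)["a", "b"]
        jc = jukes_cantor_distance(aln)["a", "b"]
        assert 0 < p < jc

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            self.aln(a="ACGT", b="ACG")

    def test_fasta_reader(self, tmp_path):
        p = tmp_path / "aln.fa"
        p.write_text(">sp1\nACGT\n>sp2\nACGA\n")
        aln = AlignedSequences.from_fasta(p)
        assert aln.names == ("sp1", "sp2")


class TestNewick:
    def test_parse_two_leaves(self):
        tree = parse_newick("(A:1,B:2);")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_round_trip_of_nj_output(self):
        planted = random_binary_tree(6, 9)
        dm = patristic_distance_matrix(planted)
        tree = neighbor_joining(dm)
        again = parse_newick(write_newick(tree))
        assert rf_distance(tree, again) == 0
        assert np.allclose(
            patristic_distance_matrix(again).values,
            patristic_distance_matrix(tree).values,
            atol=1e-10,
        )

    def test_malformed_raises(self):
        with pytest.raises(ParseError):
            parse_newick("((A,B),C;")

    def test_duplicate_leaves_raise(self):
        with pytest.raises(ParseError, match="A"):
            parse_newick("(A:1,(A:1,B:1):1);")

    def test_file_round_trip(self, tmp_path):
        tree = parse_newick("((A:1,B:2):0.5,C:3);")
        write_newick(tree, tmp_path / "t.nwk")
        again = parse_newick(tmp_path / "t.nwk")
        assert rf_distance(tree, again) == 0
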