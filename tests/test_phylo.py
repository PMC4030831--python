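"""Distances, neighbor joining, bootstrap, rooting and family groups.

scikit-bio's NJ implementation is the independent cross-check for tree
topology on additive matrices; exact edge lengths are checked against the
path-length oracle of the generating tree.
"""

import math
import random

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from conftest import additive_matrix_from_tree, make_msa, random_binary_tree

from itbkit.phylo import (
    DistanceMatrix,
    FamilyPartition,
    P_MAX,
    SaturationError,
    bootstrap_support,
    collapse_low_support,
    family_groups,
    kimura_correct,
    kimura_distance_matrix,
    neighbor_joining,
    p_distance,
)
from itbkit.tree import (
    PhyloTree,
    TreeNode,
    bipartitions,
    leaf_path_lengths,
    parse_newick,
    root_with_outgroup,
    write_newick,
)


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance("NPIY", "NPIY") == 0.0

    def test_one_in_four(self):
        assert p_distance("NPIY", "NPKY") == 0.25

    def test_all_differ(self):
        assert p_distance("AAAA", "VVVV") == 1.0

    def test_gap_columns_excluded(self):
        assert p_distance("A-CD", "AEC-") == 0.0


class TestKimuraCorrection:
    def test_zero_maps_to_zero(self):
        assert kimura_correct(0.0) == 0.0

    @pytest.mark.parametrize("p,d", [(0.1, 0.10758), (0.5, 0.79851)])
    def test_known_values(self, p, d):
        assert kimura_correct(p) == pytest.approx(d, abs=1e-5)

    def test_matches_closed_form_on_grid(self):
        for i in range(1000):
            p = i / 1000.0 * (P_MAX - 1e-9)
            assert abs(kimura_correct(p) - (-math.log(1 - p - 0.2 * p * p))) < 1e-12

    def test_monotone_and_never_below_p(self):
        grid = [i / 1000.0 * (P_MAX - 1e-9) for i in range(1000)]
        values = [kimura_correct(p) for p in grid]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(d >= p for p, d in zip(grid, values))

    def test_saturation_raises_and_names_pmax(self):
        with pytest.raises(SaturationError, match="0.854102"):
            kimura_correct(0.86)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(ids=("A", "B"), values=np.array([[0, 0.3], [0.3, 0]]))
        tree = neighbor_joining(dm)
        lengths = [c.length for c in tree.root.children]
        assert sum(lengths) == pytest.approx(0.3)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4.0], [3, 0, 5], [4, 5, 0]])
        tree = neighbor_joining(DistanceMatrix(ids=("A", "B", "C"), values=d))
        by_label = {c.label: c.length for c in tree.root.children}
        assert by_label["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert by_label["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert by_label["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxa_recovers_split_and_internal_edge(self):
        # Additive distances from ((A:1,B:2):1,(C:3,D:4)).
        ids = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(ids=ids, values=d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        internal = [
            n for n in tree.root.walk() if not n.is_leaf and n is not tree.root
        ]
        assert len(internal) == 1
        assert internal[0].length == pytest.approx(1.0)

    def test_additive_matrices_recovered_exactly(self, rng):
        """NJ reconstructs topology and edge lengths on additive inputs,
        agreeing with both the generating tree and scikit-bio's NJ."""
        for n_taxa in range(4, 9):
            for _ in range(5):
                labels = [f"T{i}" for i in range(n_taxa)]
                true = random_binary_tree(labels, rng)
                ids, d = additive_matrix_from_tree(true)
                ours = neighbor_joining(DistanceMatrix(ids=ids, values=d))
                assert bipartitions(ours) == bipartitions(true)
                ours_paths = leaf_path_lengths(ours)
                true_paths = leaf_path_lengths(true)
                for pair, dist in true_paths.items():
                    assert ours_paths[pair] == pytest.approx(dist, abs=1e-9)
                theirs = skbio_nj(SkbioDM(d, ids))
                their_splits = {
                    frozenset(t.name for t in node.tips())
                    for node in theirs.non_tips()
                }
                all_ids = frozenset(ids)
                ref = min(all_ids)
                canon = {
                    s if ref not in s else all_ids - s
                    for s in their_splits
                    if 2 <= len(s) <= n_taxa - 2
                }
                canon = {s for s in canon if 2 <= len(s) <= n_taxa - 2}
                assert bipartitions(ours) == canon

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=("A", "B"), values=np.array([[0, 1], [2, 0.0]]))


class TestNewickRoundTrip:
    def test_two_leaf_parse(self):
        tree = parse_newick("(A:1,B:2);")
        assert sorted(tree.leaf_labels()) == ["A", "B"]

    def test_unbalanced_parenthesis_rejected(self):
        with pytest.raises(ValueError, match="Newick"):
            parse_newick("((A:1,B:2;")

    def test_round_trip_on_random_trees(self, rng):
        for i in range(100):
            n = rng.randrange(2, 10)
            tree = random_binary_tree([f"L{k}" for k in range(n)], rng)
            # attach supports to internal nodes
            for node in tree.root.walk():
                if not node.is_leaf and node is not tree.root:
                    node.support = rng.randrange(0, 101)
            text = write_newick(tree)
            again = write_newick(parse_newick(text))
            assert text == again


class TestRooting:
    def test_two_taxon_tree_split_in_half(self):
        dm = DistanceMatrix(ids=("A", "B"), values=np.array([[0, 0.4], [0.4, 0]]))
        rooted = root_with_outgroup(neighbor_joining(dm), "A")
        lengths = {c.label: c.length for c in rooted.root.children}
        assert lengths == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}

    def test_missing_outgroup_rejected(self):
        tree = parse_newick("(A:1,B:2,C:1);")
        with pytest.raises(ValueError, match="not a leaf"):
            root_with_outgroup(tree, "Z")

    def test_path_lengths_preserved_on_random_trees(self, rng):
        for _ in range(50):
            n = rng.randrange(3, 10)
            labels = [f"L{k}" for k in range(n)]
            tree = random_binary_tree(labels, rng)
            before = leaf_path_lengths(tree)
            out = rng.choice(labels)
            rooted = root_with_outgroup(tree, out)
            after = leaf_path_lengths(rooted)
            for pair, dist in before.items():
                assert after[pair] == pytest.approx(dist, abs=1e-9)
            # root has the outgroup as a direct child with half its old edge
            assert any(c.label == out for c in rooted.root.children)


class TestBootstrap:
    def test_unanimous_signal_gets_support_100(self):
        # 80 invariant columns plus 20 columns that all support AB|CD.
        rows = {
            "A": "A" * 80 + "G" * 20,
            "B": "A" * 80 + "G" * 20,
            "C": "A" * 80 + "C" * 20,
            "D": "A" * 80 + "C" * 20,
        }
        tree = bootstrap_support(make_msa(rows), n_replicates=100, seed=3)
        internal = [
            n for n in tree.root.walk() if not n.is_leaf and n is not tree.root
        ]
        assert len(internal) == 1
        assert internal[0].support == 100

    def test_fixed_seed_reproducible(self):
        rows = {
            "A": "AAGGCCTTAAGGACDE",
            "B": "AAGGCCTTAAGGACDF",
            "C": "AAGGCCAAAAGGACDE",
            "D": "AAGGCCAAAAGGWCDE",
        }
        t1 = bootstrap_support(make_msa(rows), 50, seed=11)
        t2 = bootstrap_support(make_msa(rows), 50, seed=11)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_lie_in_range(self):
        rows = {
            "A": "AAGGCCTTAAGGACDE",
            "B": "AAGGCCTTAAGGACDF",
            "C": "AAGGCCAAAAGGACDE",
            "D": "AAGGCCAAAAGGWCDE",
        }
        tree = bootstrap_support(make_msa(rows), 50, seed=5)
        for node in tree.root.walk():
            if node.support is not None:
                assert 0 <= node.support <= 100

    def test_replicate_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(make_msa({"A": "AC", "B": "AD"}), 0, seed=1)


def _labelled_tree(newick: str, supports: dict[str, int] | None = None) -> PhyloTree:
    return parse_newick(newick)


class TestFamilyGroups:
    def test_single_family_single_group(self):
        tree = parse_newick("((F1_a:1,F1_b:1)100:1,(OUT:1)100:1);")
        labels = {"F1_a": "F1", "F1_b": "F1", "OUT": "OUTGROUP"}
        part = family_groups(tree, labels, 90)
        assert part.as_sorted_sets() == [["F1"]]

    def test_known_group_structure_recovered(self):
        text = (
            "(((F1_a:1,F1_b:1)99:1,(F2_a:1,F2_b:1)97:1)95:1,"
            "(F3_a:1,F3_b:1)99:1,(F4_a:1,F4_b:1)99:1,OUT:3);"
        )
        tree = parse_newick(text)
        labels = {
            "F1_a": "F1", "F1_b": "F1", "F2_a": "F2", "F2_b": "F2",
            "F3_a": "F3", "F3_b": "F3", "F4_a": "F4", "F4_b": "F4",
            "OUT": "OUTGROUP",
        }
        part = family_groups(tree, labels, 90)
        assert part.as_sorted_sets() == [["F1", "F2"], ["F3"], ["F4"]]
        assert all(part.resolved.values())

    def test_full_collapse_yields_singleton_groups(self):
        text = (
            "(((F1_a:1,F1_b:1)99:1,(F2_a:1,F2_b:1)97:1)10:1,"
            "(F3_a:1,F3_b:1)99:1,OUT:3);"
        )
        tree = parse_newick(text)
        labels = {
            "F1_a": "F1", "F1_b": "F1", "F2_a": "F2", "F2_b": "F2",
            "F3_a": "F3", "F3_b": "F3", "OUT": "OUTGROUP",
        }
        part = family_groups(tree, labels, 90)
        assert part.as_sorted_sets() == [["F1"], ["F2"], ["F3"]]

    def test_nonmonophyletic_family_merges_groups(self):
        text = "((F1_a:1,F2_a:1)99:1,(F1_b:1,F3_a:1)99:1,OUT:3);"
        tree = parse_newick(text)
        labels = {
            "F1_a": "F1", "F1_b": "F1", "F2_a": "F2", "F3_a": "F3",
            "OUT": "OUTGROUP",
        }
        part = family_groups(tree, labels, 90)
        assert part.as_sorted_sets() == [["F1", "F2", "F3"]]
        assert part.resolved["F1"] is False

    def test_unlabelled_leaf_rejected(self):
        tree = parse_newick("(A:1,B:1,OUT:1);")
        with pytest.raises(ValueError, match="unlabelled"):
            family_groups(tree, {"A": "F1", "OUT": "OUTGROUP"}, 90)

    def test_groups_must_be_disjoint(self):
        with pytest.raises(ValueError):
            FamilyPartition(
                groups=(frozenset({"F1"}), frozenset({"F1", "F2"})),
                support_threshold=90,
            )


class TestCollapse:
    def test_low_support_edges_become_polytomies(self):
        tree = parse_newick("(((A:1,B:1)50:1,C:1)95:1,D:1,E:1);")
        out = collapse_low_support(tree, 90)
        # the 50-support node dissolves; the 95 node survives
        supports = [n.support for n in out.root.walk() if not n.is_leaf]
        assert 50 not in supports and 95 in supports
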