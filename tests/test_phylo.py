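"""Distances, neighbor joining, rooting, and tree metrics."""

import math

import dendropy
import networkx as nx
import numpy as np
import pytest

from mmphylo.phylo import (Alignment, DistanceMatrix, clade_leaves,
                           jc20_correct, leaf_distance_matrix, mrca, nj_tree,
                           p_distance, patristic_distance, path_edge_count,
                           rf_distance, root_with_outgroup)
from mmphylo.synthetic import evolve_sequence, random_root_sequence

from conftest import additive_matrix, random_binary_tree


def _tree(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True,
                          suppress_internal_node_taxa=True)
    return t


class TestPDistance:
    def test_identical_rows_are_zero(self):
        d = p_distance(Alignment(ids=["a", "b"], rows=["AAAA", "AAAA"]))
        assert d.get("a", "b") == 0.0

    def test_one_mismatch_in_four(self):
        d = p_distance(Alignment(ids=["a", "b"], rows=["AAAA", "AAAC"]))
        assert d.get("a", "b") == pytest.approx(0.25)

    def test_pairwise_deletion_skips_gapped_columns(self):
        d = p_distance(Alignment(ids=["a", "b"], rows=["AA-A", "AACA"]))
        assert d.get("a", "b") == 0.0  # 3 comparable columns, 0 mismatches

    def test_ambiguity_codes_excluded(self):
        d = p_distance(Alignment(ids=["a", "b"], rows=["AXA", "ACC"]))
        assert d.get("a", "b") == pytest.approx(0.5)

    def test_selenocysteine_matches_cysteine(self):
        d = p_distance(Alignment(ids=["a", "b"], rows=["UA", "CA"]))
        assert d.get("a", "b") == 0.0

    def test_no_comparable_columns_names_the_pair(self):
        with pytest.raises(ValueError, match="'a'.*'b'"):
            p_distance(Alignment(ids=["a", "b", "c"],
                                 rows=["A--", "-A-", "AAA"]))


class TestJC20:
    def test_zero_at_zero(self):
        assert jc20_correct(0.0) == 0.0

    def test_closed_form_at_half_saturation(self):
        assert jc20_correct(0.475) == pytest.approx(0.95 * math.log(2))

    def test_saturation_boundary_errors(self):
        with pytest.raises(ValueError):
            jc20_correct(0.95)

    def test_monotone_increasing(self):
        grid = np.linspace(0, 0.9, 50)
        vals = [jc20_correct(p) for p in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_inverts_simulated_mismatch_fraction(self):
        rng = np.random.default_rng(11)
        n_sites = 1000
        for d in (0.1, 0.5, 1.0):
            root = random_root_sequence(n_sites, rng)
            child = evolve_sequence(root, d, 1.0, rng)
            p = sum(a != b for a, b in zip(root, child)) / n_sites
            est = jc20_correct(p)
            p_true = (19 / 20) * (1 - math.exp(-(20 / 19) * d))
            se_p = math.sqrt(p_true * (1 - p_true) / n_sites)
            # delta method: se(d) = se(p) / (1 - (20/19) p)
            se_d = se_p / (1 - (20 / 19) * p_true)
            assert abs(est - d) < 3 * se_d


class TestNeighborJoining:
    def test_recovers_four_taxon_tree_exactly(self):
        truth = _tree("((A:1,B:2):1,(C:3,D:4):1);")
        tree = nj_tree(additive_matrix(truth))
        assert rf_distance(tree, truth) == 0
        # additive input -> exact branch lengths (pendant edges)
        for leaf, expect in (("A", 1.0), ("B", 2.0), ("C", 3.0), ("D", 4.0)):
            node = [l for l in tree.leaf_node_iter()
                    if l.taxon.label == leaf][0]
            assert node.edge.length == pytest.approx(expect)

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(ids=["A", "B", "C"],
                           values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                                           dtype=float))
        tree = nj_tree(d)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            nj_tree(DistanceMatrix(ids=["A", "B"], values=np.zeros((2, 2))))

    def test_consistent_on_random_additive_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            truth = random_binary_tree(rng, int(rng.integers(5, 13)))
            tree = nj_tree(additive_matrix(truth))
            assert rf_distance(tree, truth) == 0

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        for _ in range(5):
            truth = random_binary_tree(rng, 8)
            dm = additive_matrix(truth)
            mine = nj_tree(dm)
            theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.values, dm.ids))
            other = _tree(str(theirs.root_at_midpoint()))
            assert rf_distance(mine, other) == 0

    def test_negative_length_estimates_clamped(self):
        d = np.array([[0, 5, 9, 9], [5, 0, 10, 10],
                      [9, 10, 0, 2], [9, 10, 2, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=list("ABCD"), values=d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    def test_four_point_condition_on_nj_output(self):
        rng = np.random.default_rng(8)
        truth = random_binary_tree(rng, 8)
        tree = nj_tree(additive_matrix(truth))
        dm = leaf_distance_matrix(tree)
        ids = dm.ids
        for _ in range(30):
            i, j, k, l = rng.choice(len(ids), size=4, replace=False)
            s1 = dm.values[i, j] + dm.values[k, l]
            s2 = dm.values[i, k] + dm.values[j, l]
            s3 = dm.values[i, l] + dm.values[j, k]
            top = sorted([s1, s2, s3])[-2:]
            assert top[0] == pytest.approx(top[1], abs=1e-9)


class TestRooting:
    def test_patristic_distances_preserved(self):
        tree = _tree("(A:1,(B:2,C:3):4);")
        rooted = root_with_outgroup(tree, "A")
        for a, b, want in (("A", "B", 7), ("A", "C", 8), ("B", "C", 5)):
            assert patristic_distance(rooted, a, b) == pytest.approx(want)

    def test_root_splits_outgroup_pendant_edge(self):
        # root lands mid-way on A's former 1-unit edge: A subtends 0.5 and
        # the ingroup 0.5 + its old 4-unit stem
        rooted = root_with_outgroup(_tree("(A:1,(B:2,C:3):4);"), "A")
        children = rooted.seed_node.child_nodes()
        assert sorted(c.edge.length for c in children) == [0.5, 4.5]
        assert any(c.is_leaf() and c.taxon.label == "A" for c in children)

    def test_rerooting_is_idempotent_up_to_isomorphism(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        once = root_with_outgroup(tree, "A")
        twice = root_with_outgroup(once, "A")
        assert rf_distance(once, twice) == 0

    def test_missing_outgroup_is_an_error(self):
        with pytest.raises(KeyError):
            root_with_outgroup(_tree("(A:1,B:1);"), "Z")


class TestPathMetrics:
    def test_hand_path_sums(self):
        tree = _tree("(A:1,(B:2,C:3):4);")
        assert patristic_distance(tree, "A", "B") == pytest.approx(7.0)
        assert patristic_distance(tree, "B", "C") == pytest.approx(5.0)
        assert patristic_distance(tree, "A", "A") == 0.0

    def test_matches_graph_shortest_path_oracle(self):
        """Independent oracle: branch-weighted shortest paths in networkx."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            tree = random_binary_tree(rng, int(rng.integers(4, 21)))
            g = nx.Graph()
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    g.add_edge(id(node), id(child),
                               weight=child.edge.length)
            leaves = {l.taxon.label: id(l) for l in tree.leaf_node_iter()}
            names = sorted(leaves)
            pick = rng.choice(len(names), size=min(5, len(names)),
                              replace=False)
            for i in pick:
                for j in pick:
                    want = nx.shortest_path_length(
                        g, leaves[names[i]], leaves[names[j]],
                        weight="weight")
                    got = patristic_distance(tree, names[i], names[j])
                    assert abs(got - want) < 1e-12

    def test_edge_count_for_sisters(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        assert path_edge_count(tree, "A", "B") == 2  # one internal node
        assert path_edge_count(tree, "A", "C") == 3


class TestCladeMachinery:
    def test_mrca_of_all_leaves_is_root(self):
        tree = _tree("((A,B),(C,D));")
        tree.is_rooted = True
        assert mrca(tree, ["A", "B", "C", "D"]) is tree.seed_node
        assert mrca(tree, ["A", "C"]) is tree.seed_node

    def test_mrca_of_single_leaf_is_the_leaf(self):
        tree = _tree("((A,B),(C,D));")
        tree.is_rooted = True
        node = mrca(tree, ["A"])
        assert node.is_leaf() and node.taxon.label == "A"

    def test_clade_leaves_of_cherry(self):
        tree = _tree("((A,B),(C,D));")
        tree.is_rooted = True
        assert clade_leaves(tree, mrca(tree, ["A", "B"])) == {"A", "B"}

    def test_unrooted_tree_rejected(self):
        tree = _tree("((A,B),(C,D));")
        tree.is_rooted = False
        with pytest.raises(ValueError, match="unrooted"):
            mrca(tree, ["A", "B"])


class TestRobinsonFoulds:
    def test_identity_is_zero(self):
        t = _tree("((A,B),(C,D));")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets_distance_two(self):
        a = _tree("((A,B),(C,D));")
        b = _tree("((A,C),(B,D));")
        assert rf_distance(a, b) == 2

    def test_invariant_under_leaf_order(self):
        a = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        b = _tree("((D:2,C:1):1,(B:3,A:1):1);")
        assert rf_distance(a, b) == 0

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf sets differ"):
            rf_distance(_tree("((A,B),C);"), _tree("((A,B),D);"))
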