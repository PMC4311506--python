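"""K2P distances, neighbor joining on additive matrices, bootstrap
supports and majority-rule consensus."""
import math

import dendropy
import numpy as np
import pytest

from rorqual import phylo
from rorqual.seqio import AlignmentMatrix, read_newick
from rorqual.synth import simulate_nt_alignment

from conftest import random_additive_tree


class TestK2P:
    def test_identical_is_zero(self):
        assert phylo.k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form_value(self):
        # P=0.1, Q=0.05 over 1000 sites
        a = "A" * 1000
        b = "G" * 100 + "C" * 50 + "A" * 850
        d = phylo.k2p_distance(a, b)
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) \
            - 0.25 * math.log(1 - 2 * 0.05)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.170181, abs=5e-7)

    def test_saturation_returns_nan(self):
        a = "A" * 10
        b = "G" * 5 + "A" * 5   # P=0.5, Q=0
        assert math.isnan(phylo.k2p_distance(a, b))

    def test_symmetry_and_pairwise_deletion(self):
        a, b = "ACGT-CGTN", "ACGAACGTA"
        assert phylo.k2p_distance(a, b) == phylo.k2p_distance(b, a)
        n, ts, tv = phylo._paired_sites(a, b)
        assert n == 7  # gap and N columns dropped


class TestTsTv:
    def test_count_ratio(self):
        a = "A" * 11 + "C" * 9
        b = "G" * 10 + "C" * 10  # 10 transitions, 1 transversion (A->C)
        aln = AlignmentMatrix(["a", "b"], [a, b])
        assert phylo.estimate_tstv(aln) == pytest.approx(10.0)

    def test_no_differences_is_nan(self):
        aln = AlignmentMatrix(["a", "b"], ["ACGT", "ACGT"])
        assert math.isnan(phylo.estimate_tstv(aln))

    def test_simulation_recovers_high_tstv(self):
        # shallow divergences pooled over several taxa, mitogenome-sized
        tree = read_newick(
            "((a:0.01,b:0.01):0.005,(c:0.01,d:0.01):0.005,"
            "(e:0.01,f:0.01):0.005);")
        aln = simulate_nt_alignment(tree, tstv=10.0, n_sites=16_435, seed=0)
        assert phylo.estimate_tstv(aln) == pytest.approx(10.0, abs=1.0)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = phylo.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = phylo.neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_four_taxon_recovery(self):
        # distances from ((a:1,b:2):1,(c:3,d:4))
        dm = phylo.DistanceMatrix(
            ["a", "b", "c", "d"],
            np.array([
                [0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0],
            ], float))
        tree = phylo.neighbor_joining(dm)
        assert phylo.bipartitions(tree) == {frozenset({"c", "d"})}
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx(
            {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})

    def test_taxon_order_invariance(self, rng):
        _, labels, dist = random_additive_tree(rng, 6)
        dm1 = phylo.DistanceMatrix(labels, dist)
        perm = rng.permutation(len(labels))
        dm2 = phylo.DistanceMatrix(
            [labels[i] for i in perm], dist[np.ix_(perm, perm)])
        t1 = phylo.neighbor_joining(dm1)
        t2 = phylo.neighbor_joining(dm2)
        assert phylo.bipartitions(t1) == phylo.bipartitions(t2)

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            tree, labels, dist = random_additive_tree(rng, n)
            nj = phylo.neighbor_joining(phylo.DistanceMatrix(labels, dist))
            assert phylo.bipartitions(nj) == phylo.bipartitions(tree)

    def test_na_entry_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = float("nan")
        with pytest.raises(ValueError, match="NA"):
            phylo.neighbor_joining(phylo.DistanceMatrix(["a", "b", "c"], m))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(
                phylo.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_branch_lengths_non_negative(self, rng):
        # noisy (non-additive) matrices can give negative NJ lengths;
        # clamping keeps them at zero
        for _ in range(10):
            _, labels, dist = random_additive_tree(rng, 5)
            noisy = dist + rng.uniform(0, 0.3, size=dist.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            tree = phylo.neighbor_joining(
                phylo.DistanceMatrix(labels, noisy))
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None:
                    assert nd.edge.length >= 0.0


class TestBootstrap:
    def test_single_replicate_supports_are_0_or_100(self):
        tree = read_newick("((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02,e:0.05);")
        aln = simulate_nt_alignment(tree, 2.0, 2000, seed=3)
        bt = phylo.bootstrap_support(aln, n_reps=1, seed=5)
        sup = set(phylo.supports(bt).values())
        assert sup <= {0.0, 100.0}

    def test_same_seed_is_reproducible(self):
        tree = read_newick("((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02,e:0.05);")
        aln = simulate_nt_alignment(tree, 2.0, 3000, seed=3)
        s1 = phylo.supports(phylo.bootstrap_support(aln, 20, seed=7))
        s2 = phylo.supports(phylo.bootstrap_support(aln, 20, seed=7))
        assert s1 == s2

    def test_identical_sequences_have_no_resolved_splits(self):
        aln = AlignmentMatrix(
            ["a", "b", "c", "d"], ["ACGTACGT"] * 4)
        bt = phylo.bootstrap_support(aln, 5, seed=1)
        assert phylo.supports(bt) == {}

    def test_invalid_rep_count(self):
        aln = AlignmentMatrix(["a", "b", "c"], ["ACGT"] * 3)
        with pytest.raises(ValueError):
            phylo.bootstrap_support(aln, 0, seed=1)

    def test_supports_bounded_and_counted(self):
        tree = read_newick(
            "((a:0.04,b:0.05):0.03,(c:0.04,d:0.05):0.03,(e:0.04,f:0.05):0.03);")
        aln = simulate_nt_alignment(tree, 2.0, 5000, seed=9)
        bt = phylo.bootstrap_support(aln, 50, seed=2)
        sup = phylo.supports(bt)
        assert all(0.0 <= v <= 100.0 for v in sup.values())
        # a binary 6-taxon tree has n-3 = 3 internal edges
        assert len(sup) == 3


class TestConsensus:
    def test_identical_trees_give_full_support(self):
        newick = "((a:1,b:1):1,(c:1,d:1):1,e:1);"
        trees = [read_newick(newick) for _ in range(4)]
        cons = phylo.majority_rule_consensus(trees)
        sup = phylo.supports(cons)
        assert set(sup.values()) == {100.0}
        assert phylo.bipartitions(cons) == phylo.bipartitions(trees[0])

    def test_even_conflict_becomes_polytomy(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        cons = phylo.majority_rule_consensus([t1, t2])
        assert phylo.bipartitions(cons) == set()

    def test_matches_dendropy_consensus(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            trees = []
            tns = None
            for _k in range(5):
                t, labels, _ = random_additive_tree(rng, n)
                if tns is None:
                    tns = t.taxon_namespace
                else:
                    t = dendropy.Tree.get(
                        data=t.as_string(schema="newick"),
                        schema="newick", taxon_namespace=tns)
                trees.append(t)
            ours = phylo.bipartitions(
                phylo.majority_rule_consensus(trees))
            tl = dendropy.TreeList(trees, taxon_namespace=tns)
            ref = tl.consensus(min_freq=0.5 + 1e-9)
            theirs = phylo.bipartitions(ref)
            assert ours == theirs

    def test_mismatched_leaf_sets_rejected(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,b),(c,e));")
        with pytest.raises(ValueError):
            phylo.majority_rule_consensus([t1, t2])
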