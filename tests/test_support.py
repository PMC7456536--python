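"""Bipartitions, consensus/BRP/TBE, RF distances, concordance, NJ."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendropy

from zpevol.support import (
    InputError,
    bipartitions,
    branch_length_concordance,
    majority_rule_consensus,
    make_bipartition,
    nj_tree,
    p_distance_matrix,
    rf_normalized,
    rf_weighted,
    tbe,
    transfer_index,
)
from zpevol.trees import Tree, parse_newick

from conftest import (
    brute_force_splits,
    brute_force_transfer_index,
    random_resolved_tree,
)


def names(n):
    return [f"t{i:02d}" for i in range(n)]


class TestBipartitions:
    def test_star_tree_has_no_bipartitions(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert bipartitions(t) == frozenset()

    @given(st.integers(min_value=4, max_value=14), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_resolved_tree_has_n_minus_3(self, n, seed):
        t = random_resolved_tree(names(n), np.random.default_rng(seed))
        assert len(bipartitions(t)) == n - 3

    def test_matches_graph_deletion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            t = random_resolved_tree(names(8), rng)
            mine = {bp.side for bp in bipartitions(t)}
            assert mine == brute_force_splits(t)


class TestConsensus:
    def test_identical_trees_full_support(self):
        rng = np.random.default_rng(0)
        t = random_resolved_tree(names(8), rng)
        sup = majority_rule_consensus([t.copy() for _ in range(5)])
        assert len(sup.branches) == 5  # n - 3
        assert all(b.brp == 1.0 for b in sup.branches)
        assert bipartitions(sup.tree) == bipartitions(t)

    def test_two_to_one_majority(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        sup = majority_rule_consensus([t1, t1.copy(), t2])
        assert len(sup.branches) == 1
        b = sup.branches[0]
        assert sorted(b.bipartition.smaller_side()) in (["A", "B"], ["C", "D"])
        assert b.brp == pytest.approx(2 / 3)

    def test_three_conflicting_quartets_give_star(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        t3 = parse_newick("((A:1,D:1):1,(B:1,C:1):1);")
        sup = majority_rule_consensus([t1, t2, t3])
        assert sup.branches == []
        assert bipartitions(sup.tree) == frozenset()

    def test_consensus_idempotent(self):
        rng = np.random.default_rng(7)
        trees = [random_resolved_tree(names(7), rng) for _ in range(4)]
        trees.append(trees[0].copy())
        sup = majority_rule_consensus(trees)
        again = majority_rule_consensus([sup.tree, sup.tree.copy()], compute_tbe=False)
        assert bipartitions(again.tree) == bipartitions(sup.tree)

    def test_tip_mismatch_is_error(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(InputError):
            majority_rule_consensus([t1, t2])

    def test_matches_dendropy_consensus(self):
        """Independent route: dendropy's majority-rule consensus."""
        rng = np.random.default_rng(12)
        newicks = [random_resolved_tree(names(8), rng).to_newick() for _ in range(7)]
        sup = majority_rule_consensus([parse_newick(s) for s in newicks])
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList(
            [dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns) for s in newicks]
        )
        dcons = tl.consensus(min_freq=0.5000001)
        dcons_mine = parse_newick(dcons.as_string(schema="newick").replace("[&U] ", ""))
        assert bipartitions(dcons_mine) == bipartitions(sup.tree)


class TestTransferIndexAndTBE:
    def test_present_bipartition_scores_zero(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        bp = make_bipartition({"A", "B"}, set("ABCD"))
        assert transfer_index(bp, t) == 0

    def test_absent_cherry_scores_one(self):
        t = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        bp = make_bipartition({"A", "B"}, set("ABCD"))
        assert transfer_index(bp, t) == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(5, 11))
            t = random_resolved_tree(names(n), rng)
            ref = random_resolved_tree(names(n), rng)
            for bp in bipartitions(ref):
                assert transfer_index(bp, t) == brute_force_transfer_index(bp.side, t)

    def test_delta_bounded_by_p_minus_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = random_resolved_tree(names(9), rng)
            ref = random_resolved_tree(names(9), rng)
            for bp in bipartitions(ref):
                assert 0 <= transfer_index(bp, t) <= bp.p - 1

    def test_tbe_one_when_always_present(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        bp = make_bipartition({"A", "B"}, set("ABCD"))
        assert tbe(bp, [t, t.copy(), t.copy()]) == 1.0

    def test_tbe_floor_at_zero_for_p2(self):
        t = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        bp = make_bipartition({"A", "B"}, set("ABCD"))
        assert tbe(bp, [t]) == 0.0

    def test_tbe_rejects_trivial_branch(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            make_bipartition({"A"}, set("ABCD"))

    def test_tbe_at_least_brp_over_replicates(self):
        rng = np.random.default_rng(2024)
        for trial in range(200):
            n = int(rng.integers(5, 9))
            trees = [random_resolved_tree(names(n), rng) for _ in range(4)]
            try:
                sup = majority_rule_consensus(trees)
            except InputError:
                continue
            for b in sup.branches:
                assert b.tbe >= b.brp - 1e-12


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        rng = np.random.default_rng(1)
        t = random_resolved_tree(names(8), rng)
        assert rf_normalized(t, t.copy()) == 0.0
        assert rf_weighted(t, t.copy()) == 0.0

    def test_conflicting_quartets_one(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_normalized(t1, t2) == 1.0
        assert rf_weighted(t1, t2) == 1.0

    def test_normalized_matches_brute_force_and_dendropy(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            t1 = random_resolved_tree(names(8), rng)
            t2 = random_resolved_tree(names(8), rng)
            s1, s2 = brute_force_splits(t1), brute_force_splits(t2)
            expect = len(s1 ^ s2) / (len(s1) + len(s2))
            assert rf_normalized(t1, t2) == pytest.approx(expect)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
            sym = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_normalized(t1, t2) == pytest.approx(sym / (len(s1) + len(s2)))

    def test_weighted_matches_brute_force_union_sum(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            t1 = random_resolved_tree(names(8), rng)
            t2 = random_resolved_tree(names(8), rng)
            # oracle: recompute split lengths via graph deletion
            def split_lens(t):
                out = {}
                for nd in t.preorder():
                    if nd is t.root or nd.is_tip:
                        continue
                    side = frozenset(x.name for x in Tree(nd).tips())
                    uni = frozenset(t.tip_names())
                    key = side if min(uni) not in side else uni - side
                    if 2 <= len(side) <= len(uni) - 2:
                        out[key] = out.get(key, 0.0) + nd.length
                return out

            l1, l2 = split_lens(t1), split_lens(t2)
            num = sum(abs(l1.get(k, 0) - l2.get(k, 0)) for k in set(l1) | set(l2))
            den = sum(l1.values()) + sum(l2.values())
            assert rf_weighted(t1, t2) == pytest.approx(num / den)

    def test_weighted_reduces_to_normalized_for_equal_lengths(self):
        rng = np.random.default_rng(8)
        t1 = random_resolved_tree(names(7), rng)
        t2 = random_resolved_tree(names(7), rng)
        for t in (t1, t2):
            for nd in t.preorder():
                if nd is not t.root:
                    nd.length = 1.0
        assert rf_weighted(t1, t2) == pytest.approx(rf_normalized(t1, t2))

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        ts = [random_resolved_tree(names(7), rng) for _ in range(3)]
        d01 = rf_normalized(ts[0], ts[1])
        d12 = rf_normalized(ts[1], ts[2])
        d02 = rf_normalized(ts[0], ts[2])
        assert d01 == rf_normalized(ts[1], ts[0])
        assert d02 <= d01 + d12 + 1e-12
        assert rf_normalized(ts[0], ts[0].copy()) == 0.0


class TestConcordance:
    def test_identical_and_scaled_vectors_are_perfectly_correlated(self):
        v = [0.1, 0.5, 0.3, 0.9]
        m = branch_length_concordance([v, v, [2 * x for x in v]])
        assert np.allclose(m, 1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        a, b = rng.uniform(size=10), rng.uniform(size=10)
        m = branch_length_concordance([a, b])
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        assert m[0, 1] == pytest.approx(float((za * zb).mean()))

    def test_zero_variance_vector_flagged_nan(self):
        m = branch_length_concordance([[1.0, 1.0, 1.0], [0.1, 0.2, 0.3]])
        assert np.isnan(m[0, 1])


class TestNeighborJoining:
    def test_recovers_additive_quartet(self):
        # AB|CD quartet: A,B differ from C,D at many sites
        rows = [
            ("A", "AAAAAAAAAAAAAAAAAAAA"),
            ("B", "AAAAAAAAAAAAAAAACCCC"),
            ("C", "GGGGGGGGGGAAAAAAAAAA"),
            ("D", "GGGGGGGGGGAAAAAACCCC"),
        ]
        t = nj_tree(rows)
        sides = {frozenset(bp.smaller_side()) for bp in bipartitions(t)}
        assert frozenset({"C", "D"}) in sides or frozenset({"A", "B"}) in sides

    def test_identical_sequences_zero_lengths(self):
        rows = [(nm, "ACDEFGHIKL") for nm in "ABCD"]
        t = nj_tree(rows)
        assert all((nd.length or 0) == 0 for nd in t.preorder() if nd is not t.root)

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        rows = [(f"s{i}", "".join(aas[rng.integers(20, size=30)])) for i in range(6)]
        assert nj_tree(rows).to_newick() == nj_tree(rows).to_newick()

    def test_missing_aware_p_distance(self):
        rows = [("A", "AC-G"), ("B", "ACXG"), ("C", "TTTG"), ("D", "AATT")]
        _, d = p_distance_matrix(rows)
        assert d[0, 1] == 0.0  # only comparable sites agree

    def test_no_comparable_sites_is_error(self):
        rows = [("A", "AC--"), ("B", "--GG"), ("C", "ACGG"), ("D", "ACGT")]
        with pytest.raises(InputError):
            nj_tree(rows)
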