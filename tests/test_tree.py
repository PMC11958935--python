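"""Decode, branch labeling, and Newick round trips — the bijection itself."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treevec as tv


def topology(v):
    return tv.decode(v).to_nested()


class TestDecode:
    def test_two_leaf_base_case(self):
        at = tv.decode([0])
        assert at.table.tolist() == [[0, 1, 2]]
        assert at.to_nested() == (0, 1)

    @pytest.mark.parametrize("v,nested", [
        ([0, 0, 4], (((0, 2), 1), 3)),   # temporary-root split places 3 outside
        ([0, 0, 0], (((0, 3), 2), 1)),   # pendant branch 0 split twice
        ([0, 0, 1], ((0, 2), (1, 3))),   # balanced birth-process tree
        ([0, 2], ((0, 1), 2)),
        ([0, 1], ((1, 2), 0)),
    ])
    def test_worked_topologies(self, v, nested):
        assert topology(v) == nested

    def test_ancestry_invariants_on_figure_example(self):
        at = tv.decode([0, 2, 2, 5, 2])
        n = at.n_leaves
        assert n == 6
        children = at.table[:, :2].ravel().tolist()
        parents = at.table[:, 2].tolist()
        # every label except the root appears exactly once as a child
        assert sorted(children) == [x for x in range(2 * n - 2)]
        # internal labels n..2n-2 each appear exactly once as a parent
        assert sorted(parents) == list(range(n, 2 * n - 1))
        assert at.root == 2 * n - 2

    def test_ordered_semantics_cherry_with_existing_leaf(self):
        # for ordered vectors, splitting pendant branch v[i] makes the new
        # leaf a cherry partner of leaf v[i]
        v = tv.validate_vector([0, 1, 0, 2])
        nested = topology(v)

        def cherries(sub, out):
            if isinstance(sub, tuple):
                a, b = sub
                if isinstance(a, int) and isinstance(b, int):
                    out.add(frozenset((a, b)))
                cherries(a, out)
                cherries(b, out)
            return out

        assert frozenset((3, 0)) in cherries(nested, set())


class TestBranchLabels:
    def test_two_leaf_tree(self):
        labs = tv.branch_labels((0, 1))
        assert labs == {frozenset([0]): 0, frozenset([1]): 1,
                        frozenset([0, 1]): 2}

    def test_three_leaf_tree_one_cherry_round(self):
        labs = tv.branch_labels(((0, 2), 1))
        assert labs[frozenset([0, 2])] == 3
        assert labs[frozenset([0, 1, 2])] == 4

    def test_four_leaf_tree_two_rounds(self):
        labs = tv.branch_labels((((0, 2), 1), 3))
        assert labs[frozenset([0, 2])] == 4
        assert labs[frozenset([0, 1, 2])] == 5
        assert labs[frozenset([0, 1, 2, 3])] == 6

    def test_labels_cover_0_to_2k_minus_2_for_every_decode_prefix(self):
        # label set is {0,...,2(k-1)} exactly once each, for every tree
        v = tv.validate_vector([0, 2, 2, 5, 2])
        for k in range(2, 7):
            labs = tv.branch_labels(tv.decode(v[: k - 1]))
            assert sorted(labs.values()) == list(range(2 * k - 1))


class TestNewick:
    @pytest.mark.parametrize("v,nw", [
        ([0], "(0,1);"),
        ([0, 2], "((0,1),2);"),
        ([0, 1], "((1,2),0);"),
        ([0, 0, 4], "(((0,2),1),3);"),
    ])
    def test_emission(self, v, nw):
        assert tv.to_newick(v, internal_labels=False) == nw

    def test_internal_labels_follow_cherry_process(self):
        assert tv.to_newick([0, 0, 4]) == "(((0,2)4,1)5,3)6;"

    @pytest.mark.parametrize("nw,v", [
        ("(((0,2),1),3);", (0, 0, 4)),
        ("(0,1);", (0,)),
    ])
    def test_parsing(self, nw, v):
        assert tuple(tv.from_newick(nw)) == v

    def test_parse_is_child_order_insensitive(self):
        assert tuple(tv.from_newick("(3,(1,(2,0)));")) == (0, 0, 4)

    def test_branch_lengths_tolerated(self):
        assert tuple(tv.from_newick("((0:0.1,1:0.2):0.3,2:0.4);")) == (0, 2)

    @pytest.mark.parametrize("bad", ["((0,1);", "((0,1),(2,3);", "(0,1,2);",
                                     "((0,1),1);", "((0,1),3);"])
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(ValueError):
            tv.from_newick(bad)

    def test_figure_vector_round_trip(self):
        v = [0, 2, 2, 5, 2]
        assert tuple(tv.from_newick(tv.to_newick(v))) == tuple(v)


class TestBijectivity:
    @pytest.mark.parametrize("n,count", [(3, 3), (4, 15), (5, 105)])
    def test_exhaustive_distinct_topologies(self, n, count):
        seen = {topology(v) for v in tv.enumerate_vectors(n)}
        assert len(seen) == count == tv.num_topologies(n)

    def test_exhaustive_round_trip_n5(self):
        for v in tv.enumerate_vectors(5):
            for labels in (True, False):
                nw = tv.to_newick(v, internal_labels=labels)
                assert tuple(tv.from_newick(nw)) == tuple(v)

    def test_ordered_subspace_counts_and_distinctness(self):
        import math
        for n in (4, 5, 6):
            ordered = [v for v in tv.enumerate_vectors(n) if tv.is_ordered(v)]
            assert len(ordered) == math.factorial(n - 1)
            assert len({topology(v) for v in ordered}) == len(ordered)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(2, 50), st.integers(0, 2**32 - 1))
    def test_round_trip_random_vectors(self, n, seed):
        v = tv.sample_vector(n, np.random.default_rng(seed))
        assert tuple(tv.from_newick(tv.to_newick(v))) == tuple(v)

    def test_as_vector_coercions_agree(self):
        v = tv.validate_vector([0, 2, 2, 5, 2])
        at = tv.decode(v)
        for form in (v, at, at.newick(), at.newick(internal_labels=False)):
            assert tuple(tv.as_vector(form)) == tuple(v)
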