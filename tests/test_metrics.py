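"""Hamming/RF distances, single-index neighborhoods, the random walk, and
the brute-force SPR oracle."""

import numpy as np
import pytest

import treevec as tv


class TestHamming:
    def test_identity_and_basic_count(self):
        v = [0, 2, 2, 5, 2]
        assert tv.hamming(v, v) == 0
        assert tv.hamming([0, 0], [0, 2]) == 1

    def test_bounded_by_n_minus_2(self, rng):
        for _ in range(20):
            v, w = tv.sample_vector(12, rng), tv.sample_vector(12, rng)
            assert tv.hamming(v, w) <= 10
            assert tv.hamming(v, w) == tv.hamming(w, v)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tv.hamming([0, 1], [0, 1, 2])


class TestRandomWalk:
    def _start(self, n, seed=0):
        v = tv.sample_vector(n, seed=seed)
        v[-1] = 2 * (n - 2)
        return v

    def test_zero_inclusion_is_identity(self, rng):
        v = self._start(10)
        step = tv.random_walk_step(v, rng, inclusion_prob=0.0)
        assert np.array_equal(step.result, v)

    def test_proposal_invariants(self, rng):
        v = self._start(30, seed=4)
        for _ in range(200):
            step = tv.random_walk_step(v, rng)
            w = step.result
            assert tv.is_valid(w)
            assert w[0] == 0 and w[-1] == v[-1]
            assert tv.hamming(v, w) <= step.indices.size
            untouched = np.setdiff1d(np.arange(v.size), step.indices)
            assert np.array_equal(w[untouched], v[untouched])
            # changed entries moved by one unit, clamped at the domain edges
            for i, s in zip(step.indices, step.signs):
                assert w[i] == min(2 * i, max(v[i] + s, 0))
            v = w

    def test_clamping_at_zero(self):
        class Forced:
            def random(self, size):
                return np.zeros(size)  # include every index

            def choice(self, options, size):
                return np.full(size, -1)  # always decrement

        v = np.zeros(6, dtype=np.int64)
        v[-1] = 10
        w = tv.random_walk_step(v, Forced()).result
        assert np.array_equal(w[:-1], np.zeros(5, dtype=np.int64))

    def test_small_trees_rejected(self, rng):
        with pytest.raises(ValueError):
            tv.random_walk_step(tv.validate_vector([0, 2]), rng)

    def test_rf_saturates_along_walk(self):
        """RF distance to the start grows then plateaus near its maximum.

        A gentle walk (2% inclusion per index) makes the rise visible;
        at larger inclusion probabilities saturation is near-immediate.
        """
        n = 200
        v0 = tv.sample_vector(n, seed=77)
        v0[-1] = 2 * (n - 2)
        checkpoints = {1, 2, 5, 10, 20, 50}
        rise, plateau = [], []
        for k, w in enumerate(tv.random_walk(v0, 5000, seed=78,
                                             inclusion_prob=0.02), start=1):
            if k in checkpoints:
                rise.append(tv.rf_distance(v0, w))
            elif k % 500 == 0:
                plateau.append(tv.rf_distance(v0, w))
        assert rise == sorted(rise)  # monotone growth over the early steps
        assert np.mean(plateau) >= rise[0]
        assert np.mean(plateau) >= 0.8 * 2 * (n - 3)  # near the RF maximum


class TestVectorNeighbors:
    def test_n3_neighborhood(self):
        nb = {tuple(w) for w in tv.vector_neighbors([0, 0])}
        assert nb == {(0, 1), (0, 2)}

    def test_count_is_quadratic(self, rng):
        for n in (2, 5, 8):
            v = tv.sample_vector(n, rng)
            nb = tv.vector_neighbors(v)
            assert len(nb) == (n - 1) * (n - 2)
            assert len({tuple(w) for w in nb}) == len(nb)  # all distinct trees


class TestRFDistance:
    def test_identity_and_known_pair(self):
        assert tv.rf_distance([0, 2, 4], [0, 2, 4]) == 0
        assert tv.rf_distance("((0,1),(2,3));", "((0,2),(1,3));") == 2

    def test_rerooting_is_rf_zero(self):
        v = tv.sample_vector(9, seed=6)
        assert tv.rf_distance(v, tv.equivalent_reroot(v, 5)) == 0

    def test_matches_own_bipartition_sets(self, rng):
        for _ in range(10):
            a, b = tv.sample_vector(8, rng), tv.sample_vector(8, rng)
            sym = len(tv.unrooted_key(a) ^ tv.unrooted_key(b))
            assert tv.rf_distance(a, b) == sym

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError):
            tv.rf_distance("((0,1),2);", "((0,1),(2,3));")


class TestSPROracle:
    def test_three_leaf_rooted_space(self):
        nb = tv.spr_neighbors([0, 1])
        assert nb == {(0, 0), (0, 2)}  # both other rooted topologies

    def test_unrooted_n5_count(self):
        v = tv.sample_vector(5, seed=9)
        v[-1] = 6
        assert len(tv.spr_neighbors(v, unrooted=True)) == 12

    @pytest.mark.parametrize("n", [6, 7, 8])
    def test_unrooted_counts_follow_quadratic(self, n):
        v = tv.sample_vector(n, seed=n)
        assert len(tv.spr_neighbors(v, unrooted=True)) == \
            2 * (n - 3) * (2 * n - 7)

    def test_source_never_in_neighborhood(self, rng):
        v = tv.sample_vector(6, rng)
        assert tuple(int(x) for x in v) not in tv.spr_neighbors(v)
        assert tv.unrooted_key(v) not in tv.spr_neighbors(v, unrooted=True)

    def test_cap_enforced(self):
        with pytest.raises(ValueError):
            tv.spr_neighbors(tv.sample_vector(13, seed=0))

    @pytest.mark.parametrize("n", [5, 6])
    def test_single_index_moves_are_spr_moves_for_ordered_vectors(self, n, rng):
        for _ in range(3):
            v = tv.sample_vector(n, rng, ordered=True)
            spr = tv.spr_neighbors(v)
            for w in tv.vector_neighbors(v):
                assert tuple(int(x) for x in w) in spr
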