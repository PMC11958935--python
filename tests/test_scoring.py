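"""JC69 pruning likelihood, Fitch parsimony, and sequence simulation."""

import math

import numpy as np
import pytest

import treevec as tv


class TestJC69:
    @pytest.mark.parametrize("b", [0.01, 0.1, 0.5, 2.0])
    def test_two_leaf_identical_site_closed_form(self, b):
        # L = (1/16)(1 + 3 e^{-8b/3}) for one shared site on a cherry
        got = tv.jc69_loglik([0], tv.Alignment(["A", "A"]), b)
        assert got == pytest.approx(math.log((1 + 3 * math.exp(-8 * b / 3)) / 16),
                                    abs=1e-12)

    def test_two_leaf_pattern_normalization(self):
        total = sum(
            math.exp(tv.jc69_loglik([0], tv.Alignment([x, y]), 0.1))
            for x in "ACGT" for y in "ACGT")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_long_branch_stationary_limit(self):
        # at b=50 the two leaves are independent: L -> (1/4)^2 per site
        got = tv.jc69_loglik([0], tv.Alignment(["A", "C"]), 50.0)
        assert got == pytest.approx(math.log(1 / 16), abs=1e-6)

    def test_missing_data_marginalizes_to_quarter(self):
        # an all-missing column contributes log(1) ... the single-site
        # likelihood of (N, A) equals the marginal P(A) = 1/4
        got = tv.jc69_loglik([0], tv.Alignment(["N", "A"]), 0.1)
        assert got == pytest.approx(math.log(0.25), abs=1e-12)

    def test_transition_matrix_rows_sum_to_one(self):
        P = tv.jc69_transition_matrix(0.37)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P > 0)

    def test_mismatched_alignment_rejected(self):
        with pytest.raises(ValueError):
            tv.jc69_loglik([0, 1], tv.Alignment(["A", "A"]), 0.1)


class TestFitch:
    def test_identical_sequences_cost_zero(self, rng):
        v = tv.sample_vector(6, rng)
        assert tv.fitch_parsimony(v, tv.Alignment(["ACGT"] * 6)) == 0

    def test_four_taxon_worked_example(self, four_taxon_alignment):
        good = tv.from_newick("((0,1),(2,3));")
        bad = tv.from_newick("((0,2),(1,3));")
        assert tv.fitch_parsimony(good, four_taxon_alignment) == 2
        assert tv.fitch_parsimony(bad, four_taxon_alignment) == 4

    def test_missing_symbols_are_free(self):
        aln = tv.Alignment(["A", "N", "-", "A"])
        v = tv.from_newick("((0,1),(2,3));")
        assert tv.fitch_parsimony(v, aln) == 0

    def test_matches_exhaustive_assignment_oracle(self, rng):
        """Brute-force minimum over all internal state assignments."""
        import itertools

        v = tv.sample_vector(5, rng)
        aln = tv.simulate_sequences(v, 6, 0.7, seed=8)
        codes = aln.codes()
        at = tv.decode(v)
        n = at.n_leaves
        total = 0
        for site in range(aln.n_sites):
            best = None
            for assign in itertools.product(range(4), repeat=n - 1):
                state = {i: int(codes[i, site]) for i in range(n)}
                state.update({n + k: assign[k] for k in range(n - 1)})
                cost = sum(state[int(c)] != state[int(p)]
                           for a, b, p in at.table for c in (a, b))
                best = cost if best is None else min(best, cost)
            total += best
        assert tv.fitch_parsimony(v, aln) == total


class TestSimulation:
    def test_zero_branch_length_copies_root(self):
        aln = tv.simulate_sequences([0, 1, 2], 50, 0.0, seed=1)
        assert len(set(aln.sequences)) == 1

    def test_seed_determinism(self):
        a = tv.simulate_sequences([0, 2, 4], 100, 0.1, seed=9)
        b = tv.simulate_sequences([0, 2, 4], 100, 0.1, seed=9)
        assert a.sequences == b.sequences

    def test_cherry_divergence_matches_jc_expectation(self):
        b = 0.1
        aln = tv.simulate_sequences([0], 10_000, b, seed=13)
        diff = np.mean([x != y for x, y in zip(*aln.sequences)])
        expected = 0.75 * (1 - math.exp(-8 * b / 3))
        assert diff == pytest.approx(expected, abs=0.02)

    def test_base_composition_roughly_uniform(self):
        aln = tv.simulate_sequences([0, 0, 1], 4000, 0.2, seed=21)
        counts = np.array([aln.sequences[0].count(c) for c in "ACGT"])
        assert counts.min() > 0.2 * counts.sum() / 4


class TestAlignment:
    def test_ragged_lengths_rejected_with_name(self):
        with pytest.raises(ValueError, match="seq_b"):
            tv.Alignment(["AAA", "AA"], names=["seq_a", "seq_b"])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            tv.Alignment(["AA", "AA"], names=["x", "x"])

    def test_unknown_symbols_rejected(self):
        with pytest.raises(ValueError):
            tv.Alignment(["AX", "AA"])
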