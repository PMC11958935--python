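"""Tree scoring: JC69 pruning likelihood, Fitch parsimony, simulation.

The likelihood engine is deliberately minimal: Jukes–Cantor (1969)
substitution (uniform base frequencies, single exchangeability) with one
global branch length applied to every edge.  That keeps the scorer
self-contained for topology search; branch-length estimation is out of
scope and can be delegated to an external engine through the generic
score-function interface of :mod:`treevec.search`.

Site patterns are compressed before scoring; gaps and ``N`` are treated
as missing data (all-ones partial likelihoods / full Fitch state sets).
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .tree import decode
from .vector import validate_vector

__all__ = [
    "jc69_transition_matrix",
    "jc69_loglik",
    "fitch_parsimony",
    "simulate_sequences",
    "JC69Score",
    "ParsimonyScore",
]


def jc69_transition_matrix(branch_length: float) -> np.ndarray:
    """JC69 transition probabilities P(t): stay 1/4 + 3/4 e^{-4t/3},
    change to each other base 1/4 - 1/4 e^{-4t/3}."""
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    e = np.exp(-4.0 * branch_length / 3.0)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    return np.full((4, 4), p_diff) + np.eye(4) * (p_same - p_diff)


def _site_patterns(codes: np.ndarray):
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return patterns, weights.astype(float)


def _check_rows(aln: Alignment, n: int, rows):
    if aln.n_rows != n:
        raise ValueError(f"alignment has {aln.n_rows} rows, tree has {n} leaves")
    if rows is None:
        return np.arange(n)
    rows = np.asarray(rows, dtype=np.int64)
    if sorted(rows.tolist()) != list(range(n)):
        raise ValueError("rows must be a permutation of 0..n-1")
    return rows


def jc69_loglik(v, aln: Alignment, branch_length: float = 0.1,
                rows=None) -> float:
    """Log-likelihood of ``decode(v)`` under JC69 with one global branch length.

    Felsenstein pruning in linear space with per-node rescaling; uniform
    (1/4) root frequencies.  ``rows`` optionally maps leaf label ->
    alignment row (used by the optimizer while labels are shuffled).
    """
    v = validate_vector(v)
    at = decode(v)
    n = at.n_leaves
    rows = _check_rows(aln, n, rows)
    if branch_length <= 0:
        raise ValueError("branch length must be positive")
    patterns, weights = _site_patterns(aln.codes())
    npat = patterns.shape[1]
    P = jc69_transition_matrix(branch_length)

    partials = np.empty((2 * n - 1, npat, 4))
    for leaf in range(n):
        obs = patterns[rows[leaf]]
        L = np.zeros((npat, 4))
        known = obs != 255
        L[known, obs[known]] = 1.0
        L[~known] = 1.0
        partials[leaf] = L
    logscale = np.zeros(npat)
    # rows are sorted by parent label = children always precede parents
    for a, b, p in at.table:
        down = (partials[a] @ P.T) * (partials[b] @ P.T)
        mx = down.max(axis=1)
        mx[mx == 0.0] = 1.0
        logscale += np.log(mx)
        partials[p] = down / mx[:, None]
    site_l = 0.25 * partials[2 * n - 2].sum(axis=1)
    return float(np.dot(weights, np.log(site_l) + logscale))


def fitch_parsimony(v, aln: Alignment, rows=None) -> int:
    """Fitch small-parsimony score (substitution count) summed over sites."""
    v = validate_vector(v)
    at = decode(v)
    n = at.n_leaves
    rows = _check_rows(aln, n, rows)
    patterns, weights = _site_patterns(aln.masks())
    npat = patterns.shape[1]
    states = np.empty((2 * n - 1, npat), dtype=np.uint8)
    for leaf in range(n):
        states[leaf] = patterns[rows[leaf]]
    changes = np.zeros(npat)
    for a, b, p in at.table:
        inter = states[a] & states[b]
        empty = inter == 0
        changes += empty
        states[p] = np.where(empty, states[a] | states[b], inter)
    return int(round(float(np.dot(weights, changes))))


def simulate_sequences(v, n_sites: int, branch_length: float = 0.1,
                       seed=None) -> Alignment:
    """Evolve i.i.d. sites down ``decode(v)`` under JC69.

    The root state is uniform over ``A C G T``; every edge uses the same
    branch length.  Returns an alignment whose row ``i`` is the sequence
    at leaf ``i``.
    """
    v = validate_vector(v)
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    at = decode(v)
    n = at.n_leaves
    e = np.exp(-4.0 * branch_length / 3.0)
    p_same = 0.25 + 0.75 * e
    states = np.empty((2 * n - 1, n_sites), dtype=np.int8)
    states[2 * n - 2] = rng.integers(0, 4, size=n_sites)
    for a, b, p in at.table[::-1]:
        for child in (a, b):
            stay = rng.random(n_sites) < p_same
            shift = rng.integers(1, 4, size=n_sites)
            states[child] = np.where(stay, states[p],
                                     (states[p] + shift) % 4)
    bases = np.array(list("ACGT"))
    return Alignment(["".join(bases[states[i]]) for i in range(n)])


class JC69Score:
    """Score function: JC69 log-likelihood (to maximize)."""

    def __init__(self, aln: Alignment, branch_length: float = 0.1):
        self.aln = aln
        self.branch_length = branch_length

    def __call__(self, v, rows=None) -> float:
        return jc69_loglik(v, self.aln, self.branch_length, rows=rows)


class ParsimonyScore:
    """Score function: negated Fitch parsimony (to maximize)."""

    def __init__(self, aln: Alignment):
        self.aln = aln

    def __call__(self, v, rows=None) -> float:
        return -float(fitch_parsimony(v, self.aln, rows=rows))
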