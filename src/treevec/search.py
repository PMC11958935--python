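"""Hill-climbing topology search over the vector space.

The optimizer's "gradient surrogate" is the neighbor matrix: entry
``(i, j)`` holds the score change from setting ``v[i] = j`` (infeasible
cells and the current value's cell are 0).  Each sweep visits every
index, takes the row-wise best strictly improving change, and the labels
are re-sent to the ordered subspace once per epoch so that every
single-index change stays within one SPR move of the current tree.
Strict improvement on finitely many trees guarantees termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relabel import apply_permutation, invert_permutation, levelorder_permutation
from .vector import validate_vector

__all__ = ["neighbor_row", "neighbor_matrix", "hill_climb", "HillClimbResult"]


def _call_score(score, v, rows):
    try:
        return float(score(v, rows=rows))
    except TypeError:
        if rows is not None and np.any(rows != np.arange(rows.size)):
            raise ValueError(
                "score function does not accept a row order; pass a scorer "
                "with a rows= keyword (e.g. JC69Score) or disable reordering"
            ) from None
        return float(score(v))


def neighbor_row(v, i: int, score, rows=None, base: float | None = None) -> np.ndarray:
    """Score changes for all single-entry modifications at position ``i``.

    Returns an array of length ``2i + 1`` (0-based position; the domain
    of ``v[i]``); the cell of the current value is 0.  Cells hold
    ``score(modified v) - score(v)``.
    """
    v = validate_vector(v)
    if not 0 <= i < v.size:
        raise ValueError(f"index {i} out of range for vector of size {v.size}")
    if base is None:
        base = _call_score(score, v, rows)
    row = np.zeros(2 * i + 1)
    w = v.copy()
    for j in range(2 * i + 1):
        if j == v[i]:
            continue
        w[i] = j
        row[j] = _call_score(score, w, rows) - base
    return row


def neighbor_matrix(v, score, rows=None) -> np.ndarray:
    """Full padded neighbor matrix, shape ``(n-1, 2n-5)``; infeasible cells 0."""
    v = validate_vector(v)
    base = _call_score(score, v, rows)
    width = 2 * (v.size - 1) + 1
    out = np.zeros((v.size, width))
    for i in range(v.size):
        r = neighbor_row(v, i, score, rows=rows, base=base)
        out[i, : r.size] = r
    return out


@dataclass
class HillClimbResult:
    """Outcome of a hill climb: best vector (in the original leaf labeling),
    its score, the accepted-score trace, and bookkeeping counters."""

    v: np.ndarray
    score: float
    trace: list[float] = field(default_factory=list)
    n_epochs: int = 0
    n_evaluations: int = 0
    # accepted moves as (vector before, vector after, new score), in the
    # shuffled labeling current at the time of the move
    moves: list[tuple[tuple, tuple, float]] = field(default_factory=list)


def hill_climb(v0, score, seed=None, max_epochs: int = 100,
               sweep: str = "shuffled", reorder: bool = True,
               tol: float = 1e-9) -> HillClimbResult:
    """Greedy single-index hill climbing to a local score maximum.

    Per epoch: optionally relabel to the ordered subspace (the data/leaf
    correspondence is composed accordingly and undone in the returned
    vector), then sweep the indices (``"shuffled"``: seeded random order
    per epoch; ``"cyclic"``: left to right), accepting at each index the
    best strictly improving single-entry change (ties broken toward the
    smallest new value; improvements below ``tol`` are ignored to avoid
    floating-point cycling).  Stops when no index improves, or at
    ``max_epochs``.

    ``score`` is called as ``score(v, rows=...)`` where ``rows[leaf]``
    is the data row carried by that leaf; plain ``score(v)`` callables
    work when ``reorder=False``.
    """
    if sweep not in ("shuffled", "cyclic"):
        raise ValueError("sweep must be 'shuffled' or 'cyclic'")
    v = validate_vector(v0)
    n = v.size + 1
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rows = np.arange(n)
    best = _call_score(score, v, rows)
    res = HillClimbResult(v=v, score=best, trace=[best], n_evaluations=1)
    for _ in range(max_epochs):
        if reorder:
            rho = levelorder_permutation(v)
            v = apply_permutation(v, rho)
            rows = rows[invert_permutation(rho)]
        indices = np.arange(1, v.size)
        if sweep == "shuffled":
            rng.shuffle(indices)
        improved = False
        for i in indices:
            w = v.copy()
            best_j, best_s = -1, best
            for j in range(2 * i + 1):
                if j == v[i]:
                    continue
                w[i] = j
                s = _call_score(score, w, rows)
                res.n_evaluations += 1
                if s > best_s + tol:
                    best_j, best_s = j, s
            if best_j >= 0:
                before = tuple(int(x) for x in v)
                v = v.copy()
                v[i] = best_j
                best = best_s
                res.trace.append(best)
                res.moves.append((before, tuple(int(x) for x in v), best))
                improved = True
        res.n_epochs += 1
        if not improved:
            break
    res.v = apply_permutation(v, rows)
    res.score = best
    return res
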