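"""Integer-vector representation of rooted binary tree topologies.

A tree with ``n`` leaves (labeled ``0..n-1``) is encoded as an integer
vector ``v`` of length ``n - 1`` whose entry at position ``i`` (0-based)
satisfies ``0 <= v[i] <= 2*i``.  The first entry is therefore always 0.
There are ``prod_i (2*i + 1) = (2n - 3)!!`` such vectors — exactly the
number of rooted binary topologies on ``n`` labeled leaves — and the
decode map (:mod:`treevec.tree`) is a bijection onto them.

Vectors satisfying the tighter bound ``v[i] <= i`` are called *ordered*;
they correspond to simple birth-process trees in which every new leaf
forms a cherry with an already-present leaf, and number ``(n - 1)!``.

Vectors are plain ``numpy`` integer arrays throughout the package.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "validate_vector",
    "is_valid",
    "is_ordered",
    "double_factorial",
    "num_topologies",
    "vector_to_index",
    "index_to_vector",
]


def validate_vector(entries: Sequence[int] | np.ndarray) -> np.ndarray:
    """Validate ``entries`` as a tree vector and return it as an int array.

    Parameters
    ----------
    entries:
        Sequence of non-negative integers of length ``n - 1``; position
        ``i`` must lie in ``{0, ..., 2*i}``.

    Returns
    -------
    numpy.ndarray
        The validated vector (int64 copy). The number of leaves is
        ``len(entries) + 1``.

    Raises
    ------
    ValueError
        If the input is empty, contains a negative entry, or violates
        the positional bound; the offending position and value are
        reported.
    """
    v = np.asarray(entries, dtype=np.int64)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("tree vector must be a non-empty 1-D integer sequence")
    bounds = 2 * np.arange(v.size, dtype=np.int64)
    bad = np.flatnonzero((v < 0) | (v > bounds))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"invalid tree vector: entry {int(v[i])} at position {i} "
            f"outside [0, {int(bounds[i])}]"
        )
    return v.copy()


def is_valid(entries: Sequence[int] | np.ndarray) -> bool:
    """True iff ``entries`` is a valid tree vector."""
    try:
        validate_vector(entries)
    except ValueError:
        return False
    return True


def is_ordered(v: Sequence[int] | np.ndarray) -> bool:
    """True iff ``v`` lies in the ordered (birth-process) subspace, v[i] <= i."""
    v = validate_vector(v)
    return bool(np.all(v <= np.arange(v.size)))


def double_factorial(m: int) -> int:
    """Exact double factorial ``m!!`` (product of every other integer down to 1).

    Computed with arbitrary-precision Python integers; ``(-1)!! = 0!! = 1``.
    """
    if m < -1:
        raise ValueError("double factorial undefined below -1")
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


def num_topologies(n_leaves: int) -> int:
    """Number of rooted binary topologies on ``n_leaves`` labeled leaves, (2n-3)!!."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    return double_factorial(2 * n_leaves - 3)


def vector_to_index(v: Sequence[int] | np.ndarray) -> int:
    """Map a tree vector to its rank in ``{0, ..., (2n-3)!! - 1}``.

    Mixed-radix encoding: position ``i`` (0-based) is a digit of radix
    ``2*i + 1``, with lower positions least significant.  Exact inverse
    of :func:`index_to_vector`.
    """
    v = validate_vector(v)
    idx = 0
    radix = 1
    for i in range(v.size):
        idx += int(v[i]) * radix
        radix *= 2 * i + 1
    return idx


def index_to_vector(idx: int, n_leaves: int) -> np.ndarray:
    """Inverse of :func:`vector_to_index` for trees on ``n_leaves`` leaves."""
    total = num_topologies(n_leaves)
    if not 0 <= idx < total:
        raise ValueError(f"index {idx} outside [0, {total}) for n={n_leaves}")
    v = np.zeros(n_leaves - 1, dtype=np.int64)
    for i in range(n_leaves - 1):
        radix = 2 * i + 1
        v[i] = idx % radix
        idx //= radix
    return v


def enumerate_entry_domains(n_leaves: int) -> Iterable[range]:
    """Per-position domains ``range(2*i + 1)`` for a tree on ``n_leaves`` leaves."""
    return (range(2 * i + 1) for i in range(n_leaves - 1))
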