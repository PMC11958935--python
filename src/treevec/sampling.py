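"""Uniform tree sampling, exhaustive enumeration, and diagnostics.

Because each vector entry ranges independently over ``{0, ..., 2i}``,
drawing every entry uniformly and independently samples rooted binary
topologies exactly uniformly — the vector space has the same cardinality
``(2n-3)!!`` as tree space and the decode map is a bijection.  The
``ordered=True`` variant draws from the birth-process subspace
(``v[i] <= i``, ``(n-1)!`` trees) instead.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .tree import from_newick, to_newick
from .vector import num_topologies, validate_vector, vector_to_index

__all__ = [
    "sample_vector",
    "enumerate_vectors",
    "unique_topologies",
    "sampling_bias_kl",
    "storage_footprint",
    "StorageFootprint",
]

DEFAULT_ENUMERATION_CAP = 8


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_vector(n_leaves: int, seed=None, ordered: bool = False) -> np.ndarray:
    """Draw one tree vector uniformly (over all trees, or ordered trees).

    ``seed`` may be an integer or a ``numpy.random.Generator`` (reused
    across calls for reproducible experiments).
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = _rng(seed)
    i = np.arange(n_leaves - 1, dtype=np.int64)
    high = (i if ordered else 2 * i) + 1  # exclusive upper bound per entry
    return rng.integers(0, high, dtype=np.int64)


def enumerate_vectors(n_leaves: int,
                      cap: int = DEFAULT_ENUMERATION_CAP) -> Iterator[np.ndarray]:
    """Yield all ``(2n-3)!!`` valid vectors in lexicographic order.

    Guarded by ``cap`` on the leaf count since the space grows as a
    double factorial.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if n_leaves > cap:
        raise ValueError(f"n_leaves={n_leaves} exceeds enumeration cap {cap}")
    for tail in itertools.product(*(range(2 * i + 1)
                                    for i in range(1, n_leaves - 1))):
        yield np.array((0,) + tail, dtype=np.int64)


def _as_vector(tree) -> tuple[int, ...]:
    if isinstance(tree, str):
        return tuple(int(x) for x in from_newick(tree))
    return tuple(int(x) for x in validate_vector(tree))


def unique_topologies(trees: Iterable) -> tuple[list[np.ndarray], np.ndarray]:
    """Deduplicate trees by topology, preserving first-seen order.

    ``trees`` may mix Newick strings and vectors (one leaf universe).
    The vector itself is the canonical key — bijectivity makes it a
    perfect hash of the rooted topology.  Returns the unique vectors and
    their multiplicities.
    """
    counts: Counter = Counter()
    order: list[tuple[int, ...]] = []
    size = None
    for t in trees:
        key = _as_vector(t)
        if size is None:
            size = len(key)
        elif len(key) != size:
            raise ValueError("trees do not share one leaf-label universe")
        if key not in counts:
            order.append(key)
        counts[key] += 1
    uniques = [np.array(k, dtype=np.int64) for k in order]
    return uniques, np.array([counts[k] for k in order], dtype=np.int64)


def sampling_bias_kl(samples: Iterable[Sequence[int]], n_leaves: int) -> float:
    """KL divergence (nats) of the empirical tree distribution from uniform.

    Each sample is ranked by :func:`~treevec.vector.vector_to_index` and
    compared against the uniform distribution on all ``(2n-3)!!``
    topologies.  Computed as ``KL(empirical || uniform)``, which is
    always finite (no smoothing needed: the reference has full support).
    """
    total = num_topologies(n_leaves)
    counts = Counter(vector_to_index(s) for s in samples)
    N = sum(counts.values())
    if N == 0:
        raise ValueError("empty sample")
    p = np.array(list(counts.values()), dtype=float) / N
    return float(np.sum(p * np.log(p * total)))


@dataclass(frozen=True)
class StorageFootprint:
    """Serialized sizes (bytes) of one topology under different encodings."""

    vector_int16: int
    vector_int32: int
    vector_text: int
    newick: int


def storage_footprint(v) -> StorageFootprint:
    """Byte sizes of ``v`` as 16/32-bit arrays, comma text, and topology-only Newick."""
    v = validate_vector(v)
    text = ",".join(str(int(x)) for x in v)
    nw = to_newick(v, internal_labels=False)
    return StorageFootprint(
        vector_int16=v.astype(np.int16).nbytes,
        vector_int32=v.astype(np.int32).nbytes,
        vector_text=len(text.encode()),
        newick=len(nw.encode()),
    )
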