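"""Leaf relabeling: permutations, level-order reordering, rerooting.

A permutation ``sigma`` of the leaf labels changes the vector but not
the tree shape, and a likelihood computed on the relabeled tree with
correspondingly permuted data is unchanged.  Reordering to the *ordered*
subspace (``v[i] <= i``) removes the asymmetry of the encoding: after
reordering, every single-index change of the vector is also a single
SPR move of the tree.

The reordering here is breadth-first flavored — shallow leaves receive
small labels — but respects the birth-process structure of ordered
trees: within every clade the two smallest labels must land in
different child subtrees (a plain left-to-right sweep per level does not
guarantee that, e.g. on the balanced four-leaf tree).  Concretely, each
subtree has a *representative* (its shallowest leaf); the two
representatives of a clade's children are labeled before anything else
inside the clade, and a clade's interior only opens up once both
representatives of its parent clade are labeled.
"""

from __future__ import annotations

import heapq
from typing import Mapping

import numpy as np

from .alignment import Alignment
from .tree import as_vector, encode_tree, tree_dicts
from .vector import validate_vector

__all__ = [
    "apply_permutation",
    "invert_permutation",
    "permute_data",
    "reorder_levelorder",
    "levelorder_permutation",
    "equivalent_reroot",
]


def invert_permutation(sigma) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=np.int64)
    inv = np.empty_like(sigma)
    inv[sigma] = np.arange(sigma.size)
    return inv


def _check_permutation(sigma, n):
    sigma = np.asarray(sigma, dtype=np.int64)
    if sigma.size != n or sorted(sigma.tolist()) != list(range(n)):
        raise ValueError(f"not a permutation of 0..{n - 1}")
    return sigma


def apply_permutation(v, sigma) -> np.ndarray:
    """Vector of the tree with every leaf ``x`` relabeled ``sigma[x]``."""
    v = validate_vector(v)
    n = v.size + 1
    sigma = _check_permutation(sigma, n)
    children, parent, root = tree_dicts(v)
    ch: dict[int, list[int]] = {}
    par: dict[int, int] = {}
    for u, cs in children.items():
        cs2 = [int(sigma[c]) if c >= 0 else c for c in cs]
        ch[u] = cs2
        for c in cs2:
            par[c] = u
    par.pop(root, None)
    return encode_tree(ch, par, root, n)


def permute_data(aln: Alignment, sigma) -> Alignment:
    """Alignment whose row ``i`` is the original row ``sigma^{-1}(i)``.

    Matches :func:`apply_permutation`: relabeled leaf ``sigma[x]`` still
    carries the data of original leaf ``x``, so likelihoods are invariant.
    """
    sigma = _check_permutation(sigma, aln.n_rows)
    return aln.take_rows(invert_permutation(sigma))


def levelorder_permutation(v) -> np.ndarray:
    """Leaf permutation ``rho`` (old label -> new label) whose application
    sends ``v`` into the ordered subspace, preferring small labels for
    shallow leaves (breadth-first flavor; ties left-to-right)."""
    v = validate_vector(v)
    n = v.size + 1
    children, parent, root = tree_dicts(v)

    # leaf priorities: (depth, breadth-first position)
    prio: dict[int, tuple[int, int]] = {}
    pos = 0
    queue = [(root, 0)]
    while queue:
        nxt = []
        for u, d in queue:
            if u >= 0:
                prio[u] = (d, pos)
                pos += 1
            else:
                for c in children[u]:
                    nxt.append((c, d + 1))
        queue = nxt

    # best (shallowest) leaf of every subtree, bottom-up
    best: dict[int, int] = {}
    order: list[int] = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(children.get(u, ()))
    for u in reversed(order):
        if u >= 0:
            best[u] = u
        else:
            a, b = children[u]
            best[u] = min(best[a], best[b], key=prio.get)

    # watchers[b]: internal nodes for which leaf b is a child representative
    watchers: dict[int, list[int]] = {}
    for u, cs in children.items():
        for c in cs:
            watchers.setdefault(best[c], []).append(u)

    done = {u: 0 for u in children}
    rho = np.empty(n, dtype=np.int64)
    label = 0
    avail: list[tuple[tuple[int, int], int]] = []
    for c in children[root]:
        heapq.heappush(avail, (prio[best[c]], best[c]))
    while avail:
        _, leaf = heapq.heappop(avail)
        rho[leaf] = label
        label += 1
        for u in watchers.get(leaf, ()):
            done[u] += 1
            if done[u] == 2:
                # clade u complete: open the second representative of each
                # internal child
                for c in children[u]:
                    if c < 0:
                        a, b = children[c]
                        second = best[a] if best[c] == best[b] else best[b]
                        heapq.heappush(avail, (prio[second], second))
    if label != n:
        raise AssertionError("reordering failed to label every leaf")
    return rho


def reorder_levelorder(v, mapping: Mapping[int, object] | None = None):
    """Relabel leaves so the same tree shape gets an ordered vector.

    Returns ``(v_ordered, mapping_new)`` where ``mapping_new[new_label]``
    is the taxon previously attached to the corresponding old label
    (``mapping`` defaults to the identity ``{i: i}``).
    """
    v = validate_vector(v)
    n = v.size + 1
    rho = levelorder_permutation(v)
    v2 = apply_permutation(v, rho)
    if mapping is None:
        mapping = {i: i for i in range(n)}
    inv = invert_permutation(rho)
    new_mapping = {new: mapping[int(inv[new])] for new in range(n)}
    return v2, new_mapping


def equivalent_reroot(v, outgroup_leaf: int) -> np.ndarray:
    """Vector of the same unrooted topology rerooted at a pendant edge.

    The returned tree has ``outgroup_leaf`` as the root's immediate
    child; under reversible substitution models with free branch lengths
    its likelihood equals that of ``decode(v)`` (pulley principle),
    while the vector Hamming distance between the two encodings is
    typically large.  (With this package's fixed global branch length
    the equality is only approximate: rerooting re-partitions the edge
    lengths around the root.)
    """
    v = validate_vector(v)
    n = v.size + 1
    if not 0 <= outgroup_leaf < n:
        raise ValueError(f"outgroup leaf must be in 0..{n - 1}")
    children, parent, root = tree_dicts(v)
    if n == 2:
        return v.copy()
    # unrooted adjacency with the old root suppressed
    adj: dict[int, set] = {}
    for u, cs in children.items():
        for c in cs:
            adj.setdefault(u, set()).add(c)
            adj.setdefault(c, set()).add(u)
    a, b = children[root]
    adj[a].discard(root)
    adj[b].discard(root)
    adj[a].add(b)
    adj[b].add(a)
    del adj[root]
    # re-root on the pendant edge of the outgroup
    start = next(iter(adj[outgroup_leaf]))
    ch: dict[int, list[int]] = {root: [outgroup_leaf, start]}
    par: dict[int, int] = {outgroup_leaf: root, start: root}
    stack = [(start, outgroup_leaf)]
    while stack:
        u, up = stack.pop()
        kids = [w for w in adj[u] if w != up]
        if kids:
            ch[u] = kids
            for w in kids:
                par[w] = u
                stack.append((w, u))
    return encode_tree(ch, par, root, n)
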