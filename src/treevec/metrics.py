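"""Distances between trees, single-index neighborhoods, random walks, and a
brute-force SPR oracle.

The vector Hamming distance counts differing entries; a constrained
random walk perturbs a subset of entries by +/-1 (clamped to each
entry's domain), holding the first entry at 0 and the last at its
maximum ``2(n-2)`` so that the walk moves through unrooted tree space.
Robinson–Foulds distances are delegated to :mod:`dendropy`.  The SPR
(subtree prune and regraft) neighborhoods are enumerated by brute force
for small trees — a test oracle, not a search tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .tree import as_vector, decode, encode_tree, to_newick, tree_dicts
from .vector import validate_vector

__all__ = [
    "hamming",
    "WalkProposal",
    "random_walk_step",
    "random_walk",
    "vector_neighbors",
    "rf_distance",
    "spr_neighbors",
    "unrooted_key",
]

DEFAULT_SPR_CAP = 12


def hamming(v, w) -> int:
    """Number of positions at which two tree vectors differ."""
    v = validate_vector(v)
    w = validate_vector(w)
    if v.size != w.size:
        raise ValueError("vectors must have equal length")
    return int(np.count_nonzero(v != w))


@dataclass(frozen=True)
class WalkProposal:
    """One step of the constrained random walk."""

    source: np.ndarray
    indices: np.ndarray   # 0-based positions that were perturbed
    signs: np.ndarray     # +1 / -1 per perturbed position
    result: np.ndarray


def random_walk_step(v, rng, inclusion_prob: float = 0.5) -> WalkProposal:
    """Perturb a random subset of interior entries of ``v`` by +/-1.

    Each position ``i`` in ``1 .. n-3`` (0-based; the first and last
    entries are pinned) enters the subset independently with probability
    ``inclusion_prob``; included entries move up or down one unit with
    equal probability, clamped to ``[0, 2i]``.  Requires
    ``v[-1] == 2(n-2)`` so the walk stays in unrooted tree space.
    """
    v = validate_vector(v)
    n = v.size + 1
    if n < 4:
        raise ValueError("walk needs at least 4 leaves (no interior indices)")
    if v[-1] != 2 * (n - 2):
        raise ValueError("walk requires the last entry pinned at 2(n-2)")
    cand = np.arange(1, n - 2)
    include = rng.random(cand.size) < inclusion_prob
    idx = cand[include]
    signs = rng.choice((-1, 1), size=idx.size)
    w = v.copy()
    w[idx] = np.minimum(2 * idx, np.maximum(v[idx] + signs, 0))
    return WalkProposal(source=v, indices=idx, signs=signs, result=w)


def random_walk(v0, steps: int, seed=None,
                inclusion_prob: float = 0.5) -> Iterator[np.ndarray]:
    """Yield the successive vectors of a ``steps``-long random walk from ``v0``."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    v = validate_vector(v0)
    for _ in range(steps):
        v = random_walk_step(v, rng, inclusion_prob).result
        yield v


def vector_neighbors(v) -> list[np.ndarray]:
    """All vectors differing from ``v`` in exactly one position.

    There are exactly ``sum_i 2i = (n-1)(n-2)`` of them and, by
    bijectivity, they all encode distinct rooted topologies.
    """
    v = validate_vector(v)
    out = []
    for i in range(1, v.size):
        for j in range(2 * i + 1):
            if j != v[i]:
                w = v.copy()
                w[i] = j
                out.append(w)
    return out


# ---------------------------------------------------------------------------
# Robinson–Foulds
# ---------------------------------------------------------------------------

def _as_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    return to_newick(as_vector(tree), internal_labels=False)


def rf_distance(a, b) -> int:
    """Robinson–Foulds distance between the unrooted versions of two trees.

    Symmetric difference of the non-trivial bipartition sets; inputs may
    be vectors, Newick strings, or ancestry tables over the same leaf
    set.
    """
    import dendropy
    from dendropy.calculate import treecompare

    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=_as_newick(a), schema="newick",
                           taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=_as_newick(b), schema="newick",
                           taxon_namespace=ns)
    if ({x.taxon.label for x in t1.leaf_node_iter()}
            != {x.taxon.label for x in t2.leaf_node_iter()}):
        raise ValueError("trees do not share one leaf set")
    t1.is_rooted = False
    t2.is_rooted = False
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(treecompare.symmetric_difference(t1, t2))


# ---------------------------------------------------------------------------
# brute-force SPR oracle
# ---------------------------------------------------------------------------

def _subtree_nodes(children, x) -> set:
    out = set()
    stack = [x]
    while stack:
        u = stack.pop()
        out.add(u)
        stack.extend(children.get(u, ()))
    return out


def _copy(children, parent):
    return {u: list(c) for u, c in children.items()}, dict(parent)


def spr_neighbors(tree, unrooted: bool = False,
                  cap: int = DEFAULT_SPR_CAP) -> set:
    """All distinct topologies one SPR move away from ``tree``, by brute force.

    Rooted mode returns canonical vector tuples of the neighboring
    rooted trees (pruning any non-root subtree, regrafting on any
    remaining branch including above the root).  Unrooted mode operates
    on the unrooted version and returns canonical bipartition-set keys
    (see :func:`unrooted_key`).  The source topology is never included.
    """
    v = as_vector(tree)
    n = v.size + 1
    if n > cap:
        raise ValueError(f"n={n} exceeds SPR enumeration cap {cap}")
    if unrooted:
        return _spr_unrooted(v, n)
    return _spr_rooted(v, n)


def _spr_rooted(v, n) -> set:
    children, parent, root = tree_dicts(v)
    source = tuple(int(x) for x in v)
    nodes = list(parent.keys()) + [root]
    out = set()
    for x in nodes:
        if x == root:
            continue
        p = parent[x]
        pruned = _subtree_nodes(children, x)
        remaining = [y for y in nodes if y not in pruned and y != p]
        for y in remaining:
            ch, par = _copy(children, parent)
            # detach x: collapse p onto x's sibling
            a, b = ch[p]
            sib = a if b == x else b
            if p == root:
                new_root = sib
                par.pop(sib, None)
            else:
                new_root = root
                g = par[p]
                gcs = ch[g]
                gcs[gcs.index(p)] = sib
                par[sib] = g
            del ch[p]
            par.pop(p, None)
            par.pop(x, None)
            # regraft above y, reusing p as the new internal node
            if y == new_root:
                ch[p] = [y, x]
                par[y] = p
                par[x] = p
                new_root = p
            else:
                g = par[y]
                gcs = ch[g]
                gcs[gcs.index(y)] = p
                ch[p] = [y, x]
                par[p] = g
                par[y] = p
                par[x] = p
            key = tuple(int(t) for t in encode_tree(ch, par, new_root, n))
            if key != source:
                out.add(key)
    return out


def _adjacency(v, n) -> dict:
    """Unrooted adjacency map of the decoded tree (root suppressed)."""
    children, parent, root = tree_dicts(v)
    adj: dict[int, set] = {}
    for u, cs in children.items():
        for c in cs:
            adj.setdefault(u, set()).add(c)
            adj.setdefault(c, set()).add(u)
    if n >= 3:
        a, b = children[root]
        adj[a].discard(root)
        adj[b].discard(root)
        adj[a].add(b)
        adj[b].add(a)
        del adj[root]
    return adj


def _component(adj, start, blocked) -> set:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w != blocked and w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def unrooted_key(adj_or_tree, n_leaves: int | None = None) -> frozenset:
    """Canonical key for an unrooted topology: its non-trivial splits,
    each represented by the leaf side not containing leaf 0."""
    if isinstance(adj_or_tree, dict):
        adj = adj_or_tree
        n = n_leaves
    else:
        v = as_vector(adj_or_tree)
        n = v.size + 1
        adj = _adjacency(v, n)
    splits = set()
    # orient away from leaf 0 and accumulate leaf sets below each edge
    order = []
    parent = {0: None}
    stack = [0]
    while stack:
        u = stack.pop()
        order.append(u)
        for w in adj[u]:
            if w != parent[u]:
                parent[w] = u
                stack.append(w)
    below = {u: (frozenset([u]) if u >= 0 else frozenset()) for u in order}
    for u in reversed(order):
        if parent[u] is not None:
            below[parent[u]] = below[parent[u]] | below[u]
    for u in order:
        if parent[u] is not None:
            s = below[u]
            if 1 < len(s) < n - 1:
                splits.add(s)
    return frozenset(splits)


def _spr_unrooted(v, n) -> set:
    if n < 4:
        raise ValueError("unrooted SPR needs at least 4 leaves")
    adj = _adjacency(v, n)
    source = unrooted_key(adj, n)
    out = set()
    for u in list(adj):
        if len(adj[u]) != 3:
            continue
        for x in list(adj[u]):
            # prune the component hanging from x across the edge (u, x)
            a, b = sorted(adj[u] - {x})
            pruned = _component(adj, x, blocked=u)
            d_nodes = set(adj) - pruned - {u}
            # remaining-tree edges, including the edge (a, b) created by
            # suppressing u
            edges = {(a, b)}
            for c in d_nodes:
                for d in adj[c]:
                    if d in d_nodes and d != u and c < d:
                        edges.add((c, d))
            for c, d in edges:
                new = {k: set(s) for k, s in adj.items()}
                # suppress u
                new[a].discard(u)
                new[b].discard(u)
                new[x].discard(u)
                new[a].add(b)
                new[b].add(a)
                del new[u]
                # subdivide (c, d) with u and hang x
                new[c].discard(d)
                new[d].discard(c)
                new[u] = {c, d, x}
                new[c].add(u)
                new[d].add(u)
                new[x].add(u)
                key = unrooted_key(new, n)
                if key != source:
                    out.add(key)
    return out
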