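"""Decoding vectors to trees, branch labeling, and Newick round trips.

The decode map builds a rooted binary tree from a vector ``v`` by a
branch-splitting process.  Start from the two-leaf tree on leaves 0 and 1,
augmented with a *temporary root* attached above the true root, so that a
tree with ``k`` leaves exposes exactly ``2k - 1`` branches.  Branches are
labeled: the pendant branch of leaf ``i`` is labeled ``i``, the
temporary-root branch is labeled ``2(k - 1)``, and internal branches get
labels ``k .. 2k - 3`` by iterative cherry picking: repeatedly take the
cherry whose larger member ``cmax`` is maximal over all current cherries,
label the branch above it with the next label, prune leaf ``cmax``, and
continue.  Then, reading ``v`` left to right, entry ``v[i]`` names the
branch that is split to attach leaf ``i + 1``.  The temporary root exists
only during this construction.

The same cherry-picking labels, computed on the finished tree, name its
internal nodes ``n .. 2n - 2`` (the root is always ``2n - 2``, the label
of the temporary-root branch).  On the ordered subspace this coincides
with naming ancestors in last-in-first-out order of leaf addition.

The inverse map prunes leaves in descending order: removing leaf ``j``
exposes the branch it was attached to, whose label in the pruned tree is
``v[j]``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .vector import validate_vector

__all__ = [
    "AncestryTable",
    "decode",
    "to_newick",
    "from_newick",
    "branch_labels",
]

_TEMP_ROOT = -1  # internal working ids are negative; leaves are >= 0


# ---------------------------------------------------------------------------
# cherry-picking branch labels
# ---------------------------------------------------------------------------

def _cherry_process(children, parent, root, first_label,
                    target_node=None, target_label=None):
    """Label non-root internal nodes by iterative cherry picking.

    Labels start at ``first_label`` (= current leaf count).  If
    ``target_node`` is given, returns its label as soon as assigned; if
    ``target_label`` is given, returns the node that receives it;
    otherwise returns the full ``{node: label}`` dict.  The input tree is
    not modified.
    """
    ch = {u: list(cs) for u, cs in children.items()}
    par = dict(parent)
    heap = []
    for u, cs in ch.items():
        if len(cs) == 2 and cs[0] >= 0 and cs[1] >= 0 and u != root:
            heapq.heappush(heap, (-max(cs), u))
    labels = {}
    lab = first_label
    while heap:
        neg_cmax, u = heapq.heappop(heap)
        labels[u] = lab
        if target_node is not None and u == target_node:
            return lab
        if target_label is not None and lab == target_label:
            return u
        lab += 1
        # prune leaf cmax: u collapses onto its remaining (smaller) leaf
        cmax = -neg_cmax
        a, b = ch[u]
        keep = a if b == cmax else b
        g = par[u]
        gcs = ch[g]
        gcs[gcs.index(u)] = keep
        par[keep] = g
        if g != root and gcs[0] >= 0 and gcs[1] >= 0:
            heapq.heappush(heap, (-max(gcs), g))
    if target_node is not None or target_label is not None:
        raise ValueError("branch label not found; malformed tree or label out of range")
    return labels


def _display_key(node, labels):
    # internal children first (deeper labels first), then leaves ascending
    if node < 0:
        return (0, -labels[node])
    return (1, node)


# ---------------------------------------------------------------------------
# ancestry table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestryTable:
    """Rooted binary tree as ``n - 1`` triples ``(child_a, child_b, parent)``.

    Node labels: leaves ``0 .. n-1``; internal nodes ``n .. 2n-2`` named by
    the cherry-picking branch labels of the finished tree, so the root is
    always ``2n - 2``.  Rows are sorted by parent label, which is a valid
    bottom-up (postorder) evaluation order since every internal node is
    labeled before its parent.
    """

    table: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.table, dtype=np.int64)
        if t.ndim != 2 or t.shape[1] != 3 or t.shape[0] < 1:
            raise ValueError("ancestry table must have shape (n-1, 3)")
        object.__setattr__(self, "table", t)

    @property
    def n_leaves(self) -> int:
        return self.table.shape[0] + 1

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def children_map(self) -> dict[int, tuple[int, int]]:
        return {int(p): (int(a), int(b)) for a, b, p in self.table}

    def to_nested(self):
        """Topology as nested tuples of leaf labels."""
        ch = self.children_map()

        def build(u):
            if u < self.n_leaves:
                return u
            a, b = ch[u]
            return (build(a), build(b))

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * self.n_leaves + 100))
        try:
            return build(self.root)
        finally:
            sys.setrecursionlimit(old)

    def newick(self, internal_labels: bool = True,
               names: Mapping[int, str] | None = None) -> str:
        """Serialize to a semicolon-terminated Newick string (topology only).

        ``names`` optionally maps leaf labels to taxon names.
        """
        ch = self.children_map()
        out = []
        stack = [self.root]
        while stack:
            item = stack.pop()
            if isinstance(item, str):
                out.append(item)
            elif item not in ch:
                out.append(str(item) if names is None else str(names[item]))
            else:
                a, b = ch[item]
                close = f"){item}" if internal_labels else ")"
                stack.extend([close, b, ",", a, "("])
        return "".join(out) + ";"

    def bipartitions(self) -> frozenset[frozenset[int]]:
        """Non-trivial unrooted bipartitions, each given as the leaf side not
        containing leaf 0.  A canonical key for unrooted topology identity."""
        n = self.n_leaves
        below: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
        splits = set()
        for a, b, p in self.table:
            s = below[int(a)] | below[int(b)]
            below[int(p)] = s
            if 0 in s:
                s = frozenset(range(n)) - s
            if 1 < len(s) < n - 1:
                splits.add(s)
        return frozenset(splits)


# ---------------------------------------------------------------------------
# decode / encode
# ---------------------------------------------------------------------------

def _split_branch(children, parent, x, new_internal, new_leaf):
    p = parent[x]
    cs = children[p]
    cs[cs.index(x)] = new_internal
    children[new_internal] = [x, new_leaf]
    parent[new_internal] = p
    parent[x] = new_internal
    parent[new_leaf] = new_internal


def decode(v) -> AncestryTable:
    """Decode a tree vector into its :class:`AncestryTable`.

    Entry ``v[i]`` is the label of the branch split to attach leaf
    ``i + 1`` to the growing (temporary-rooted) tree; see the module
    docstring for the labeling rule.
    """
    v = validate_vector(v)
    n = v.size + 1
    children = {_TEMP_ROOT: [-2], -2: [0, 1]}
    parent = {-2: _TEMP_ROOT, 0: -2, 1: -2}
    nxt = -3
    for i in range(1, n - 1):
        k = i + 1  # current number of leaves
        b = int(v[i])
        root = children[_TEMP_ROOT][0]
        if b < k:
            x = b
        elif b == 2 * (k - 1):
            x = root
        else:
            x = _cherry_process(children, parent, root, first_label=k,
                                target_label=b)
        _split_branch(children, parent, x, nxt, i + 1)
        nxt -= 1
    root = children[_TEMP_ROOT][0]
    del children[_TEMP_ROOT]
    del parent[root]
    return _finalize(children, parent, root, n)


def _finalize(children, parent, root, n) -> AncestryTable:
    """Name internal nodes with the final cherry-picking labels and emit rows."""
    if n == 2:
        return AncestryTable(np.array([[0, 1, 2]], dtype=np.int64))
    labels = _cherry_process(children, parent, root, first_label=n)
    labels[root] = 2 * n - 2
    rows = []
    for u, lab in labels.items():
        a, b = sorted(children[u], key=lambda c: _display_key(c, labels))
        rows.append((labels.get(a, a) if a < 0 else a,
                     labels.get(b, b) if b < 0 else b,
                     lab))
    rows.sort(key=lambda r: r[2])
    return AncestryTable(np.array(rows, dtype=np.int64))


def encode_tree(children, parent, root, n) -> np.ndarray:
    """Encode a rooted binary tree (leaves ``0..n-1``, internal ids negative)
    as a vector, by pruning leaves in descending order.  Mutates its inputs."""
    v = np.zeros(n - 1, dtype=np.int64)
    for leaf in range(n - 1, 1, -1):
        p = parent[leaf]
        a, b = children[p]
        sib = a if b == leaf else b
        if p == root:
            root = sib
            parent.pop(sib, None)
        else:
            g = parent[p]
            gcs = children[g]
            gcs[gcs.index(p)] = sib
            parent[sib] = g
        del children[p]
        del parent[leaf]
        parent.pop(p, None)
        i = leaf - 1
        k = leaf  # leaves remaining
        if sib >= 0:
            v[i] = sib
        elif sib == root:
            v[i] = 2 * (k - 1)
        else:
            v[i] = _cherry_process(children, parent, root, first_label=k,
                                   target_node=sib)
    return v


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def to_newick(v, internal_labels: bool = True) -> str:
    """Decode ``v`` and serialize it as a Newick string.

    Children are emitted internal-subtree-first (internal nodes by
    descending label, then leaves ascending), which makes the output
    deterministic and reproduces conventional small examples, e.g.
    ``to_newick([0, 0, 4])`` is ``(((0,2)4,1)5,3)6;``.
    """
    return decode(v).newick(internal_labels=internal_labels)


def _tree_from_dendropy(nw: str):
    import dendropy

    try:
        t = dendropy.Tree.get(data=nw, schema="newick",
                              suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises its own error hierarchy
        raise ValueError(f"could not parse Newick string: {exc}") from None
    children: dict[int, list[int]] = {}
    parent: dict[int, int] = {}
    ids: dict[object, int] = {}
    nxt = -2
    leaves = []
    for node in t.preorder_node_iter():
        kids = node.child_nodes()
        if len(kids) == 0:
            if node.taxon is None or node.taxon.label is None:
                raise ValueError("unlabeled leaf in Newick string")
            try:
                lab = int(str(node.taxon.label))
            except ValueError:
                raise ValueError(
                    f"leaf label {node.taxon.label!r} is not an integer; map "
                    "taxon names to integers first (see treevec.io)"
                ) from None
            ids[node] = lab
            leaves.append(lab)
        elif len(kids) == 2:
            ids[node] = nxt
            nxt -= 1
        else:
            raise ValueError(
                f"non-binary node with {len(kids)} children in Newick string"
            )
    n = len(leaves)
    if sorted(leaves) != list(range(n)):
        raise ValueError(f"leaf labels must be exactly 0..{n - 1} with no "
                         "duplicates or gaps")
    for node in t.preorder_node_iter():
        kids = node.child_nodes()
        if kids:
            u = ids[node]
            children[u] = [ids[c] for c in kids]
            for c in kids:
                parent[ids[c]] = u
    root = ids[t.seed_node]
    return children, parent, root, n


def from_newick(nw: str) -> np.ndarray:
    """Encode a Newick tree (integer leaf labels ``0..n-1``) as a vector.

    Exact inverse of :func:`to_newick` for any child ordering; branch
    lengths, comments and internal-node labels are tolerated and ignored.
    """
    children, parent, root, n = _tree_from_dendropy(nw)
    if n < 2:
        raise ValueError("tree must have at least 2 leaves")
    return encode_tree(children, parent, root, n)


def _coerce_tree(tree):
    """Accept nested tuples of ints, AncestryTable, or Newick text."""
    if isinstance(tree, AncestryTable):
        tree = tree.to_nested()
    if isinstance(tree, str):
        return _tree_from_dendropy(tree)[:3]
    children: dict[int, list[int]] = {}
    parent: dict[int, int] = {}
    counter = [-2]

    def build(sub):
        if isinstance(sub, int):
            return sub
        if len(sub) != 2:
            raise ValueError("non-binary node in nested tree")
        u = counter[0]
        counter[0] -= 1
        children[u] = [build(sub[0]), build(sub[1])]
        for c in children[u]:
            parent[c] = u
        return u

    root = build(tuple(tree))
    return children, parent, root


def as_vector(tree) -> np.ndarray:
    """Coerce a vector-like, Newick string, or :class:`AncestryTable` to a vector."""
    if isinstance(tree, AncestryTable):
        return from_newick(tree.newick(internal_labels=False))
    if isinstance(tree, str):
        return from_newick(tree)
    return validate_vector(tree)


def tree_dicts(v) -> tuple[dict, dict, int]:
    """Children/parent dicts (internal ids negative) for a decoded vector.

    Internal node label ``L`` (``n .. 2n-2``) maps to id ``-(L - n + 2)``,
    so the root is ``-n``.  Used by neighborhood enumeration and
    relabeling code that edits trees structurally.
    """
    at = decode(v)
    n = at.n_leaves

    def nid(lab):
        lab = int(lab)
        return -(lab - n + 2) if lab >= n else lab

    children: dict[int, list[int]] = {}
    parent: dict[int, int] = {}
    for a, b, p in at.table:
        u = nid(p)
        children[u] = [nid(a), nid(b)]
        parent[nid(a)] = u
        parent[nid(b)] = u
    return children, parent, -n


def branch_labels(tree) -> dict[frozenset, int]:
    """Branch labels of a ``k``-leaf rooted tree plus its temporary-root branch.

    Branches are keyed by the set of leaves below them.  Pendant branches
    get their leaf's label, the temporary-root branch (above the root;
    keyed by the full leaf set) gets ``2(k - 1)``, and internal branches
    get ``k .. 2(k - 1) - 1`` by the iterative cherry-picking rule.

    ``tree`` may be nested tuples of ints, an :class:`AncestryTable`, or a
    Newick string.
    """
    children, parent, root = _coerce_tree(tree)
    leaves = sorted(u for u in parent if u >= 0)
    if root >= 0:
        raise ValueError("tree must have at least 2 leaves")
    k = len(leaves)
    if sorted(leaves) != list(range(k)):
        raise ValueError(f"leaves must be labeled 0..{k - 1}")
    node_labels = _cherry_process(children, parent, root, first_label=k)
    node_labels[root] = 2 * (k - 1)
    below: dict[int, frozenset] = {}

    def clade(u):
        if u >= 0:
            return frozenset([u])
        if u not in below:
            a, b = children[u]
            below[u] = clade(a) | clade(b)
        return below[u]

    out = {frozenset([i]): i for i in leaves}
    for u, lab in node_labels.items():
        out[clade(u)] = lab
    return out
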