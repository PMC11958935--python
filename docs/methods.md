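# Methods

## The vector–tree bijection

A rooted binary topology on leaves `0..n-1` is encoded as an integer
vector `v` of length `n-1` with `0 <= v[i] <= 2i` (0-based positions;
`v[0] = 0`). Decoding grows the tree leaf by leaf. A temporary root is
attached above the true root so that a tree with `k` leaves exposes
exactly `2k - 1` branches, labeled:

- pendant branch of leaf `i`: label `i`;
- temporary-root branch: label `2(k-1)`;
- internal branches: labels `k .. 2k-3`, assigned by iterative cherry
  picking — among all current cherries take the one whose larger
  member `cmax` is maximal, label the branch above it with the next
  label, prune leaf `cmax`, repeat.

Entry `v[i]` names the branch split to attach leaf `i+1`. Since every
step offers `2i + 1` choices, the number of vectors equals the number
of rooted topologies `(2n-3)!!`, and injectivity (verified here by
exhaustive enumeration for n ≤ 6: 3, 15, 105, 945 distinct topologies)
makes the map a bijection. Encoding inverts the construction by
pruning leaves in descending order: removing leaf `j` exposes the
branch it was attached to, whose label in the pruned tree is `v[j]`.
The implementation keeps a max-heap of cherries, giving roughly
quadratic worst-case work per conversion; a 1000-leaf tree converts in
well under a second, which is ample for the intended desk scale. No
attempt is made at the asymptotically faster balanced-tree variant, and
Newick input with pre-labeled internal nodes is parsed but not used as
a shortcut.

### Naming and serialization conventions

Internal nodes of a finished tree are named `n .. 2n-2` by the same
cherry-picking labels; the root is always `2n-2` (the temporary-root
branch). On the ordered subspace this coincides with naming ancestors
in last-in-first-out order of leaf addition. Newick output lists
internal children before leaf children (internal nodes by descending
label, leaves ascending), making emission deterministic; parsing is
insensitive to child order. The `AncestryTable` rows are sorted by
parent label, which is simultaneously a valid postorder for likelihood
evaluation.

Vectors are stored with the always-zero first entry so that printed
examples and file formats correspond position-for-position to the
mathematical definition. Taxon names are kept outside the vector in a
two-column taxon↔integer mapping (`treevec.io`).

## Ordered trees and reordering

Vectors with `v[i] <= i` describe birth processes: each new leaf forms
a cherry with an existing leaf. Every tree shape can be relabeled into
this subspace. The constraint that matters is recursive: inside every
clade, the two smallest labels must end up in *different* child
subtrees (the clade's root is created when its second subtree receives
its first leaf). A naive left-to-right, level-by-level relabeling
violates this on the balanced four-leaf tree — `((0,1),(2,3))` encodes
to `[0,2,2]`, which is not ordered — so `reorder_levelorder` uses a
constrained breadth-first scheme: each subtree has a representative
(its shallowest, leftmost leaf); the two representatives of the root
are labeled first, and a clade's interior becomes eligible only after
both representatives of its parent clade are labeled, with eligible
leaves always labeled in (depth, breadth-first position) order. This
provably lands in the ordered subspace (checked exhaustively for all
1,068 topologies with n ≤ 6), is idempotent in shape, and reduces to
plain level order on ladder trees. Ties within a level follow the
emitted child order.

Relabeling by a permutation σ and permuting alignment rows by σ⁻¹
leaves both likelihood and parsimony scores exactly unchanged; this is
tested to 1e-9 and exploited by the optimizer.

## Sampling and diagnostics

`sample_vector` draws each entry independently and uniformly, which is
exactly uniform over topologies; a single seeded
`numpy.random.Generator` can be threaded through all stochastic
operations. The bias diagnostic ranks samples with the mixed-radix
index and reports `KL(empirical ‖ uniform)`, which is always finite
(the uniform reference has full support), so no smoothing constant is
needed; the expected value under perfect sampling is about
`(K-1)/(2N)` nats for `K` topologies and `N` draws. A chi-square
goodness-of-fit test complements it. Storage figures compare the int16
array (2 bytes/entry), the comma-separated text form, and topology-only
Newick.

## Distances, walks, neighborhoods

The Hamming distance counts differing entries. The random walk
perturbs a random subset of the interior positions `1..n-3` by ±1
(clamped to each domain), pinning `v[0] = 0` and `v[n-2] = 2(n-2)` so
successive trees share an outgroup and the walk effectively moves
through unrooted space. The per-index inclusion probability is a free
parameter (default 0.5; the saturation demonstration in the tests uses
0.02, where the rise of the Robinson–Foulds distance before its
plateau near `2(n-3)` is visible rather than immediate).

Robinson–Foulds distances are computed by dendropy on the unrooted
trees; an independent bipartition-set implementation backs the SPR
deduplication keys and cross-checks dendropy in the tests.

The SPR neighborhoods are brute-force oracles (default cap n ≤ 12).
The rooted variant prunes every non-root subtree and regrafts on every
remaining branch, including above the root; the unrooted variant
operates on the suppressed-root adjacency directly. Brute force for
n = 6..10 confirms the distinct unrooted SPR neighborhood size
`2(n-3)(2n-7)` against the single-entry move count `(n-1)(n-2)`; the
ratio of these quadratics at n = 10⁴ is ≈ 3.9986, the "about four
times larger" relationship, and for ordered vectors every single-entry
move is verified to lie inside the rooted SPR neighborhood.

## Scoring

`jc69_loglik` is Felsenstein pruning under Jukes–Cantor: uniform base
frequencies, `P(same) = 1/4 + 3/4·e^{-4b/3}`, one global branch length
`b` on every edge (default 0.1 expected substitutions/site — a
moderate divergence typical of the virus-scale alignments this kind of
search targets). Site patterns are compressed once per alignment;
partials are rescaled per node to avoid underflow; gaps, `N` and `?`
are missing data (all-ones partials). Two-leaf closed forms and the
pattern-probability normalization serve as exact oracles in the tests.

Fixing one global branch length keeps the scorer self-contained but has
one visible consequence: the pulley principle holds only approximately,
so different rootings of the same unrooted topology can differ slightly
in score. The optimizer therefore solves a slightly harder (rooted)
problem than a branch-length-optimizing engine would; any external
scorer can be substituted through the same score-function interface.

`fitch_parsimony` is the standard bitmask small-parsimony count, with
missing symbols contributing the full state set; an exhaustive
assignment enumeration validates it on small instances.

`simulate_sequences` evolves i.i.d. sites from a uniform root state
down the decoded tree with the same JC69 kernel. It emulates the
idealized regime the scorer assumes — equal branch lengths, no rate
heterogeneity, no indels (gaps appear only if put in by hand), no
compositional bias — so recovery results on simulated data demonstrate
correctness of the search machinery, not robustness to model
misspecification on real alignments.

## Hill climbing

The optimizer maintains the neighbor matrix implicitly: for index `i`,
the row of score changes over `j ∈ {0..2i}` (current cell 0). A sweep
visits every index (seeded random order per epoch by default, or
cyclic), accepting the row-best change if it improves the score by more
than `1e-9` (guarding against floating-point cycling); ties break
toward the smallest `j` for determinism. Once per epoch the labels are
reordered into the ordered subspace — keeping single-entry moves inside
the SPR framework — with the leaf→data-row mapping composed
accordingly and undone in the returned vector. Strict improvement over
a finite space guarantees termination; the accepted-score trace is
strictly increasing by construction. Index sweeps are
without-replacement within an epoch; a with-replacement flavor is
equivalent up to the epoch bookkeeping and not separately implemented.

## Problem sizes

The test and acceptance workloads are chosen to run comfortably on a
laptop-class single core: exhaustive enumeration to n = 6 (945 trees),
SPR brute force to n = 10, 10⁵ draws for the uniformity checks, 1000
round trips at n = 50, a 5000-step walk at n = 200 with distances
sampled every 250 steps, and topology recovery on 8 leaves × 2000
sites from 10 random starts. The whole suite finishes in well under a
minute.

## Known limitations

- Branch lengths are not stored, estimated, or optimized; multifurcating
  trees are rejected.
- The SPR oracle is exhaustive only (no heuristic SPR search, no exact
  or approximate SPR distances; Kuhner–Felsenstein distance is out of
  scope since it needs branch lengths).
- The likelihood engine is JC69-only with one global branch length; no
  rate heterogeneity or richer substitution models.
- Hill climbing changes one entry at a time and can in principle stall
  at rooting-induced local optima (see the pulley note above);
  `equivalent_reroot` offers an escape move but is not applied
  automatically.
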