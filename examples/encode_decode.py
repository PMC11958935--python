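"""Round-tripping a tree between its vector and Newick forms.

A rooted binary topology on n leaves is one integer vector of length
n-1 with 0 <= v[i] <= 2i.  Decoding splits the branch named v[i] to
attach leaf i+1; the branch names come from an iterative cherry-picking
rule, so the encoding is exact in both directions.
"""

import treevec as tv

v = [0, 2, 2, 5, 2]
print("vector:         ", v)
print("newick:         ", tv.to_newick(v, internal_labels=False))
print("newick (labeled):", tv.to_newick(v))

w = tv.from_newick(tv.to_newick(v))
print("round trip:     ", w.tolist(), "(identical to the input)")

# the branch labels of a small temporary-rooted tree, keyed by the
# leaves below each branch; the temporary-root branch is always 2(k-1)
print("branch labels of ((0,2),1):")
for clade, label in sorted(tv.branch_labels(((0, 2), 1)).items(), key=lambda x: x[1]):
    print(f"   {set(clade)} -> {label}")

# every topology also has a single integer rank below (2n-3)!!
idx = tv.vector_to_index(v)
print("rank:", idx, "of", tv.num_topologies(6), "6-leaf trees")
print("back:", tv.index_to_vector(idx, 6).tolist())
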