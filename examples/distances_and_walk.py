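"""Vector moves, tree distances, and a random walk through tree space.

Changing a single vector entry is a small, SPR-like topological move:
there are (n-1)(n-2) such moves, roughly a quarter of the distinct SPR
neighborhood.  A random walk that perturbs a few entries per step drives
the Robinson-Foulds distance to the start upward until it saturates
near its maximum 2(n-3).
"""

import numpy as np

import treevec as tv

n = 100
v0 = tv.sample_vector(n, seed=4)
v0[-1] = 2 * (n - 2)  # pin the last entry: move through unrooted space

print(f"single-index moves from one {n}-leaf tree:",
      len(tv.vector_neighbors(v0)), "= (n-1)(n-2)")

small = tv.sample_vector(8, seed=4)
small[-1] = 12
print("8-leaf tree: distinct SPR neighbors =",
      len(tv.spr_neighbors(small, unrooted=True)),
      "vs single-index moves =", len(tv.vector_neighbors(small)))

print("\nstep  hamming  rf   (max rf =", 2 * (n - 3), ")")
for k, w in enumerate(tv.random_walk(v0, 400, seed=5, inclusion_prob=0.05),
                      start=1):
    if k in (1, 5, 25, 100, 400):
        print(f"{k:4d}  {tv.hamming(v0, w):7d}  {tv.rf_distance(v0, w):3d}")

# rerooting changes the vector a lot but the unrooted topology not at all
w = tv.equivalent_reroot(v0, 42)
print("\nreroot at leaf 42: hamming =", tv.hamming(v0, w),
      " rf =", tv.rf_distance(v0, w))
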