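"""Uniform tree sampling, a bias diagnostic, and storage costs.

Because the vector entries are independent uniform digits, sampling
vectors samples rooted topologies exactly uniformly.  The KL divergence
of the empirical distribution of tree ranks from the uniform reference
should be tiny (it decays like (K-1)/2N for K topologies and N draws).
"""

import numpy as np

import treevec as tv

rng = np.random.default_rng(1)

samples = [tv.sample_vector(5, rng) for _ in range(20_000)]
kl = tv.sampling_bias_kl(samples, 5)
print(f"KL(empirical || uniform) over 105 five-leaf trees: {kl:.5f} nats")

uniques, counts = tv.unique_topologies(samples)
print(f"distinct topologies seen: {len(uniques)} / 105, "
      f"count range {counts.min()}..{counts.max()}")

# vectors are far cheaper to store than Newick text for large trees
for n in (10, 100, 1000):
    fp = tv.storage_footprint(tv.sample_vector(n, rng))
    print(f"n={n:5d}  int16: {fp.vector_int16:5d} B   text: "
          f"{fp.vector_text:5d} B   newick: {fp.newick:6d} B")
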