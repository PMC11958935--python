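import numpy as np
import pytest

import treevec as tv


@pytest.fixture
def rng():
    return np.random.default_rng(20240001)


@pytest.fixture
def four_taxon_alignment():
    """Two cherries of identical sequences: parsimony optimum ((0,1),(2,3))."""
    return tv.Alignment(["AA", "AA", "CC", "CC"])
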