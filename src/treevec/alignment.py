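"""Leaf-indexed nucleotide alignments used by the scoring functions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Alignment"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MISSING = {"-", "N", "?"}
# Fitch state bitmasks: A=1, C=2, G=4, T=8; missing = all four
_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}


@dataclass
class Alignment:
    """Equal-length nucleotide sequences; row index = leaf label.

    Symbols are ``A C G T`` plus ``- N ?`` for missing data (treated as
    fully ambiguous by both likelihood and parsimony).
    """

    sequences: list[str]
    names: list[str] | None = field(default=None)

    def __post_init__(self):
        self.sequences = [s.upper() for s in self.sequences]
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        L = len(self.sequences[0])
        for i, s in enumerate(self.sequences):
            if len(s) != L:
                name = self.names[i] if self.names else f"row {i}"
                raise ValueError(
                    f"sequence {name!r} has length {len(s)}, expected {L}")
            bad = set(s) - set("ACGT") - _MISSING
            if bad:
                raise ValueError(f"unsupported symbols {sorted(bad)} in row {i}")
        if self.names is not None:
            if len(self.names) != len(self.sequences):
                raise ValueError("names/sequences length mismatch")
            if len(set(self.names)) != len(self.names):
                raise ValueError("duplicate sequence identifiers")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix: A=0 C=1 G=2 T=3, missing=255."""
        out = np.full((self.n_rows, self.n_sites), 255, dtype=np.uint8)
        for i, s in enumerate(self.sequences):
            out[i] = [_CODE.get(c, 255) for c in s]
        return out

    def masks(self) -> np.ndarray:
        """(n, L) uint8 state bitmasks (A=1 C=2 G=4 T=8, missing=15)."""
        out = np.empty((self.n_rows, self.n_sites), dtype=np.uint8)
        for i, s in enumerate(self.sequences):
            out[i] = [_MASK.get(c, 15) for c in s]
        return out

    def take_rows(self, order) -> "Alignment":
        """New alignment whose row ``i`` is this alignment's row ``order[i]``."""
        order = np.asarray(order, dtype=np.int64)
        if sorted(order.tolist()) != list(range(self.n_rows)):
            raise ValueError("row order must be a permutation of all rows")
        names = [self.names[j] for j in order] if self.names else None
        return Alignment([self.sequences[j] for j in order], names)
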