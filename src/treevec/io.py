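"""File I/O: Newick with taxon-name mapping, FASTA alignments, vector text.

Trees with non-integer taxon names are mapped to integer leaf labels by
first-encounter order in the Newick string; the mapping is persisted as
a two-column (taxon, integer) text file so vectors remain meaningful
across runs.  Vectors are stored as comma-separated integers, one per
line (the leading 0 included).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .alignment import Alignment
from .tree import decode
from .vector import validate_vector

__all__ = [
    "read_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "read_vectors",
    "write_vectors",
    "read_taxon_mapping",
    "write_taxon_mapping",
]


def read_newick(path_or_text) -> tuple[str, dict[int, str]]:
    """Read a Newick tree; return (integer-labeled Newick, label -> taxon map).

    Branch lengths and comments are stripped.  If every leaf label is
    already an integer the mapping is the identity on those labels;
    otherwise taxa are numbered 0.. by first-encounter order.
    """
    import dendropy

    text = str(path_or_text)
    p = Path(text)
    if not text.lstrip().startswith("(") and p.is_file():
        text = p.read_text().strip()
    try:
        t = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"could not parse Newick input: {exc}") from None
    labels = []
    for leaf in t.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label is None:
            raise ValueError("unlabeled leaf in Newick input")
        labels.append(str(leaf.taxon.label))
    n = len(labels)
    try:
        ints = [int(x) for x in labels]
        if sorted(ints) == list(range(n)):
            mapping = {i: str(i) for i in ints}
        else:
            raise ValueError
    except ValueError:
        mapping = dict(enumerate(labels))
    taxon_to_int = {tax: i for i, tax in mapping.items()}
    for leaf in t.leaf_node_iter():
        leaf.taxon.label = str(taxon_to_int[str(leaf.taxon.label)])
    nw = t.as_string(schema="newick", suppress_rooting=True,
                     suppress_edge_lengths=True,
                     suppress_internal_node_labels=True,
                     unquoted_underscores=True).strip()
    return nw, mapping


def write_newick(tree, path, mapping: Mapping[int, str] | None = None,
                 internal_labels: bool = False) -> None:
    """Write a vector or ancestry table as Newick, optionally with taxon names."""
    at = tree if hasattr(tree, "newick") else decode(validate_vector(tree))
    Path(path).write_text(
        at.newick(internal_labels=internal_labels, names=mapping) + "\n")


def read_fasta(path) -> Alignment:
    """Read a FASTA alignment; record order defines the leaf index."""
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(seqs, names)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(aln.sequences):
            name = aln.names[i] if aln.names else str(i)
            fh.write(f">{name}\n{seq}\n")


def read_vectors(path) -> list[np.ndarray]:
    """Read vectors from text: comma-separated integers, one vector per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(validate_vector([int(x) for x in line.split(",")]))
    return out


def write_vectors(vectors, path) -> None:
    with open(path, "w") as fh:
        for v in vectors:
            fh.write(",".join(str(int(x)) for x in validate_vector(v)) + "\n")


def read_taxon_mapping(path) -> dict[int, str]:
    """Read a two-column (taxon, integer) mapping file."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            taxon, idx = line.rsplit("\t", 1)
            mapping[int(idx)] = taxon
    return mapping


def write_taxon_mapping(mapping: Mapping[int, str], path) -> None:
    with open(path, "w") as fh:
        for idx in sorted(mapping):
            fh.write(f"{mapping[idx]}\t{idx}\n")
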