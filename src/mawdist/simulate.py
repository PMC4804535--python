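"""Synthetic inputs for validation.

Three generators back the package's property tests and examples:

* `random_dna_record` / `random_records` — i.i.d. uniform DNA strings.
  Real coding sequences are not i.i.d. (codon structure, GC bias), but
  for testing word-set algebra only the combinatorics of factors matter,
  and uniform strings exercise those fully.
* `random_additive_matrix` — path-length matrix of a random edge-weighted
  binary tree; the exact fixed point neighbor joining must recover.
* `random_ultrametric_matrix` — cophenetic matrix of a random clock-like
  agglomeration; the exact fixed point UPGMA must recover.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .matrix import DistanceMatrix
from .sequences import DNA, Alphabet, SeqRecord

__all__ = [
    "random_dna_record",
    "random_records",
    "random_additive_matrix",
    "random_ultrametric_matrix",
    "write_fasta",
]


def random_dna_record(
    rng: np.random.Generator,
    length: int,
    record_id: str = "seq",
    alphabet: Alphabet = DNA,
) -> SeqRecord:
    """A single uniform-random record over *alphabet* (one segment)."""
    seq = "".join(rng.choice(list(alphabet.symbols), size=length))
    return SeqRecord(record_id, (seq,), alphabet)


def random_records(
    rng: np.random.Generator,
    n: int,
    length: int,
    alphabet: Alphabet = DNA,
) -> list[SeqRecord]:
    """*n* independent uniform-random records, ids s01, s02, ..."""
    width = max(2, len(str(n)))
    return [
        random_dna_record(rng, length, f"s{i + 1:0{width}d}", alphabet) for i in range(n)
    ]


def _labels(n: int) -> tuple[str, ...]:
    return tuple(f"T{i + 1:02d}" for i in range(n))


def random_additive_matrix(
    rng: np.random.Generator,
    n_leaves: int,
    min_edge: float = 0.1,
    max_edge: float = 1.0,
) -> tuple[DistanceMatrix, TreeNode]:
    """An exactly additive matrix and the random tree that realizes it.

    Leaves T01..Tnn are joined pairwise in random order; every edge gets
    an independent uniform length in [min_edge, max_edge]. The matrix
    entries are the leaf-to-leaf path lengths of the resulting tree.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves for an interesting additive matrix")
    labels = _labels(n_leaves)
    clusters: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b = clusters.pop(j)
        a = clusters.pop(i)
        a.length = float(rng.uniform(min_edge, max_edge))
        b.length = float(rng.uniform(min_edge, max_edge))
        clusters.append(TreeNode(children=[a, b]))
    a, b = clusters
    # final edge split arbitrarily across the root; path lengths are unaffected
    total = float(rng.uniform(min_edge, max_edge))
    a.length, b.length = total / 2.0, total / 2.0
    tree = TreeNode(children=[a, b])
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    order = [ids.index(lab) for lab in labels]
    values = np.asarray(dm.data)[np.ix_(order, order)]
    return DistanceMatrix(labels, values), tree


def random_ultrametric_matrix(
    rng: np.random.Generator,
    n_leaves: int,
    min_step: float = 0.1,
    max_step: float = 1.0,
) -> DistanceMatrix:
    """A random exactly ultrametric (clock-like) matrix on T01..Tnn.

    Clusters are merged in random order at strictly increasing heights;
    the distance between two leaves is twice the height of their first
    common cluster.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    labels = _labels(n_leaves)
    index = {lab: i for i, lab in enumerate(labels)}
    values = np.zeros((n_leaves, n_leaves))
    clusters: list[list[str]] = [[lab] for lab in labels]
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(min_step, max_step))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b = clusters.pop(j)
        a = clusters.pop(i)
        for la in a:
            for lb in b:
                values[index[la], index[lb]] = values[index[lb], index[la]] = 2.0 * height
        clusters.append(a + b)
    return DistanceMatrix(labels, values)


def write_fasta(records: list[SeqRecord], path) -> None:
    """Write noRC records to FASTA (segments joined with an N separator)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            fh.write("N".join(r.segments) + "\n")
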