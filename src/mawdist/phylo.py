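"""Distance-based tree reconstruction: UPGMA and neighbor joining.

Both agglomerations are implemented here rather than delegated, so that
tie-breaking is fully deterministic: when two candidate merges score
equally, the pair whose (lexicographically smallest member, then second
member) label pair sorts first is chosen. Trees are `skbio.TreeNode`
objects — rooted ultrametric for UPGMA, unrooted (trifurcating root) for
NJ. Negative NJ branch-length estimates are clamped to zero; the raw
estimate is kept on the node as ``preclamp_length``.

Both methods require non-negative dissimilarities; matrices from indices
that can go negative should be passed through
:meth:`mawdist.matrix.DistanceMatrix.shifted_nonnegative` first.
"""

from __future__ import annotations

import re
from itertools import combinations

import numpy as np
from skbio import TreeNode

from .matrix import DistanceMatrix
from .sequences import ValidationError

__all__ = ["upgma", "neighbor_joining", "to_newick", "path_length_matrix"]


def _check_matrix(m: DistanceMatrix) -> None:
    if m.min_offdiagonal() < 0:
        raise ValidationError(
            "matrix has negative entries; apply shifted_nonnegative() before tree building"
        )


def _clamped(node: TreeNode, length: float) -> TreeNode:
    node.preclamp_length = length
    node.length = max(length, 0.0)
    return node


def upgma(m: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration producing a rooted ultrametric tree.

    Cluster heights are half the merge distances; on an exactly
    ultrametric input the cophenetic distances of the result reproduce
    the input.
    """
    _check_matrix(m)
    # cluster key = lexicographically smallest member label (deterministic ties)
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in m.labels}
    sizes: dict[str, int] = {lab: 1 for lab in m.labels}
    heights: dict[str, float] = {lab: 0.0 for lab in m.labels}
    dist: dict[tuple[str, str], float] = {}
    for a, b in combinations(m.labels, 2):
        dist[tuple(sorted((a, b)))] = m[a, b]

    while len(nodes) > 1:
        pair = min(dist, key=lambda p: (dist[p], p))
        a, b = pair
        d = dist.pop(pair)
        height = d / 2.0
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = height - heights.pop(a)
        nb.length = height - heights.pop(b)
        merged = TreeNode(children=[na, nb])
        key = min(a, b)
        new_size = sizes[a] + sizes[b]
        for c in list(nodes):
            if c == key:
                continue
            da = dist.pop(tuple(sorted((a, c))))
            db = dist.pop(tuple(sorted((b, c))))
            dist[tuple(sorted((key, c)))] = (sizes[a] * da + sizes[b] * db) / new_size
        sizes.pop(a), sizes.pop(b)
        sizes[key] = new_size
        nodes[key] = merged
        heights[key] = height
    root = next(iter(nodes.values()))
    root.length = None
    return root


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the Q-criterion.

    Returns an unrooted tree serialized with a trifurcating root
    (a two-taxon matrix yields a root splitting the single edge evenly).
    Exactly additive inputs are recovered: the path-length matrix of the
    result equals the input. Negative branch-length estimates are clamped
    to zero, with the raw value kept as ``preclamp_length``.
    """
    _check_matrix(m)
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in m.labels}
    dist: dict[tuple[str, str], float] = {}
    for a, b in combinations(m.labels, 2):
        dist[tuple(sorted((a, b)))] = m[a, b]

    if len(nodes) == 2:
        (a, na), (b, nb) = sorted(nodes.items())
        d = dist[(a, b)]
        _clamped(na, d / 2.0)
        _clamped(nb, d / 2.0)
        return TreeNode(children=[na, nb])

    def d_of(a: str, b: str) -> float:
        return dist[tuple(sorted((a, b)))]

    while len(nodes) > 3:
        n = len(nodes)
        keys = sorted(nodes)
        r = {k: sum(d_of(k, c) for c in keys if c != k) for k in keys}
        best = min(
            (((n - 2) * d_of(a, b) - r[a] - r[b], (a, b)) for a, b in combinations(keys, 2)),
            key=lambda t: (t[0], t[1]),
        )
        a, b = best[1]
        dab = d_of(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        na, nb = nodes.pop(a), nodes.pop(b)
        merged = TreeNode(children=[_clamped(na, la), _clamped(nb, lb)])
        key = min(a, b)
        dist.pop((min(a, b), max(a, b)))
        for c in list(nodes):
            da = dist.pop(tuple(sorted((a, c))))
            db = dist.pop(tuple(sorted((b, c))))
            dist[tuple(sorted((key, c)))] = 0.5 * (da + db - dab)
        nodes[key] = merged

    (a, na), (b, nb), (c, nc) = sorted(nodes.items())
    dab, dac, dbc = d_of(a, b), d_of(a, c), d_of(b, c)
    _clamped(na, 0.5 * (dab + dac - dbc))
    _clamped(nb, 0.5 * (dab + dbc - dac))
    _clamped(nc, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[na, nb, nc])


_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9_.\-|]+$")


def _format_label(name: str) -> str:
    if _PLAIN_LABEL.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _newick_node(node: TreeNode, precision: int) -> str:
    if node.is_tip():
        s = _format_label(node.name or "")
    else:
        s = "(" + ",".join(_newick_node(c, precision) for c in node.children) + ")"
        if node.name:
            s += _format_label(node.name)
    if node.length is not None:
        s += f":{node.length:.{precision}f}"
    return s


def to_newick(t: TreeNode, precision: int = 6) -> str:
    """Newick string with branch lengths at the given decimal precision."""
    return _newick_node(t, precision) + ";"


def path_length_matrix(t: TreeNode, labels: tuple[str, ...]) -> np.ndarray:
    """Leaf-to-leaf path lengths of a tree, ordered by *labels*."""
    dm = t.tip_tip_distances()
    ids = list(dm.ids)
    idx = [ids.index(lab) for lab in labels]
    return np.asarray(dm.data)[np.ix_(idx, idx)]
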