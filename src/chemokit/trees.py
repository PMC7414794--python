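"""Neighbor-joining trees with column-resampling bootstrap support.

NJ agglomeration itself is delegated to scikit-bio; this module adds
protein p-distances from an alignment, bipartition extraction, and
bootstrap support (fraction of replicate trees containing each internal
bipartition of the original tree, resampling alignment columns with
replacement).
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


def nj_tree(matrix, labels: list[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix."""
    arr = np.asarray(matrix, dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    return nj(DistanceMatrix(arr, ids=labels))


def p_distance_matrix(alignment: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances over an aligned set of sequences; columns
    where either sequence has a gap are ignored for that pair."""
    labels = list(alignment)
    seqs = [alignment[l] for l in labels]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    n = len(labels)
    mat = np.zeros((n, n))
    arr = np.array([list(s) for s in seqs])
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            denom = ok.sum()
            d = float((arr[i][ok] != arr[j][ok]).mean()) if denom else 0.0
            mat[i, j] = mat[j, i] = d
    return mat, labels


def bipartitions(tree: TreeNode, taxa: set[str] | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, each canonicalized as the
    side not containing the alphabetically first taxon."""
    if taxa is None:
        taxa = {t.name for t in tree.tips()}
    ref = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa) - len(side) < 2:
            continue
        if ref in side:
            side = frozenset(taxa - side)
        parts.add(side)
    return parts


def bootstrap_nj(alignment: dict[str, str], replicates: int = 1000,
                 seed: int = 0) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree from an alignment with bootstrap support.

    Columns are resampled with replacement ``replicates`` times; support
    for each internal bipartition of the original tree is the fraction
    of replicate trees containing it. Supports are written onto the
    internal node names of the returned tree (as fractions in [0, 1]).
    """
    rng = np.random.default_rng(seed)
    labels = list(alignment)
    taxa = set(labels)
    length = len(next(iter(alignment.values())))
    mat, _ = p_distance_matrix(alignment)
    tree = nj_tree(mat, labels)
    target = bipartitions(tree, taxa)
    hits = {part: 0 for part in target}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {l: "".join(alignment[l][c] for c in cols) for l in labels}
        rmat, _ = p_distance_matrix(resampled)
        rparts = bipartitions(nj_tree(rmat, labels), taxa)
        for part in target:
            hits[part] += part in rparts
    support = {part: hits[part] / replicates for part in target}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if min(taxa) in side:
            side = frozenset(taxa - side)
        if side in support:
            node.name = f"{support[side]:.3f}"
    return tree, support


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()
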