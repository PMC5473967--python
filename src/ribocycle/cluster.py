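"""Profile dissimilarities and average-linkage clustering of the four
organ x assay rhythmic traces.

For each gene, a 4x4 matrix of Euclidean distances between its four
replicate-averaged 12-point log2 profiles (kidney-RNA, kidney-RPF, liver-RNA,
liver-RPF) is computed; gene matrices are fused by a weighted elementwise
mean, and the fused matrix is clustered with average linkage. The tree's
first merge reveals whether footprint rhythms resemble each other across
organs more than they resemble their own organ's mRNA rhythms.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .dataio import ValidationError

log = logging.getLogger("ribocycle")


def profile_dissimilarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between one gene's time profiles.

    ``profiles`` holds one row per organ x assay trace (typically 4) and one
    column per timepoint; missing values are not allowed.
    """
    if profiles.isna().any().any():
        raise ValidationError("profile matrix contains missing timepoints")
    d = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def fuse(matrices: Sequence[pd.DataFrame],
         weights: Sequence[float] | None = None) -> pd.DataFrame:
    """Weighted elementwise mean of per-gene dissimilarity matrices."""
    if not matrices:
        raise ValidationError("no matrices to fuse")
    if weights is None:
        weights = np.ones(len(matrices))
    w = np.asarray(weights, dtype=float)
    if w.size != len(matrices):
        raise ValidationError("one weight per matrix required")
    if (w < 0).any() or w.sum() == 0:
        raise ValidationError("weights must be non-negative and not all zero")
    ref = matrices[0]
    acc = np.zeros_like(ref.to_numpy(dtype=float))
    for m, wi in zip(matrices, w):
        if m.shape != ref.shape or not m.index.equals(ref.index):
            raise ValidationError("dissimilarity matrices do not align")
        acc += wi * m.to_numpy(dtype=float)
    return pd.DataFrame(acc / w.sum(), index=ref.index, columns=ref.columns)


def hcluster(matrix: pd.DataFrame, linkage: str = "average",
             ) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of a dissimilarity matrix.

    Returns the scipy linkage matrix and the leaf labels in the order used.
    Labels are sorted lexicographically beforehand so that ties in merge
    heights break deterministically.
    """
    labels = sorted(matrix.index)
    m = matrix.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(m, m.T) or (np.diag(m) != 0).any() or (m < 0).any():
        raise ValidationError("not a valid dissimilarity matrix")
    Z = hierarchy.linkage(squareform(m, checks=False), method=linkage)
    return Z, labels


def first_merge(Z: np.ndarray, labels: Sequence[str]) -> frozenset[str]:
    """Labels of the two clusters joined first (singleton leaves only)."""
    i, j = int(Z[0, 0]), int(Z[0, 1])
    members = []
    for idx in (i, j):
        if idx >= len(labels):
            raise ValidationError("first merge involves a non-leaf cluster")
        members.append(labels[idx])
    return frozenset(members)


def to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
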