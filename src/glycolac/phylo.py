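"""Glyco-phylogenetics: distance matrices over motif profiles and UPGMA
dendrograms.

Entities (species, individuals, samples) are compared by the cosine
distance of their motif-abundance profiles, or by cosine distance over the
presence/absence of terminal motifs; UPGMA (average linkage with
cluster-size weighting) then yields an ultrametric dendrogram, exportable
to newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "cosine_distance_matrix",
    "binary_distance_matrix",
    "upgma",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with entity labels."""

    matrix: np.ndarray
    labels: list

    def __post_init__(self):
        d = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = np.clip(d, 0, None)

    @property
    def n(self) -> int:
        return len(self.labels)


def _cosine(profiles: np.ndarray, labels) -> DistanceMatrix:
    norms = np.linalg.norm(profiles, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero profile rows: {[labels[i] for i in zero]}")
    unit = profiles / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, list(labels))


def cosine_distance_matrix(profiles) -> DistanceMatrix:
    """Pairwise cosine distances d = 1 − u·v/(|u||v|) of profile rows.

    Accepts a DataFrame (index = entity labels) or an array plus implicit
    integer labels.  Scale-invariant per row.
    """
    import pandas as pd

    if isinstance(profiles, pd.DataFrame):
        return _cosine(profiles.to_numpy(dtype=float), list(profiles.index))
    arr = np.asarray(profiles, dtype=float)
    return _cosine(arr, list(range(arr.shape[0])))


def binary_distance_matrix(presence, metric: str = "cosine") -> DistanceMatrix:
    """Distances over 0/1 terminal-motif presence vectors.

    Default cosine on the binary vectors; ``metric="jaccard"`` available.
    """
    import pandas as pd

    if isinstance(presence, pd.DataFrame):
        arr, labels = presence.to_numpy(dtype=float), list(presence.index)
    else:
        arr = np.asarray(presence, dtype=float)
        labels = list(range(arr.shape[0]))
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("presence matrix must be 0/1")
    if metric == "cosine":
        return _cosine(arr, labels)
    if metric == "jaccard":
        inter = arr @ arr.T
        sums = arr.sum(axis=1)
        union = sums[:, None] + sums[None, :] - inter
        if (sums == 0).any():
            raise ValueError("all-zero presence rows")
        d = 1.0 - inter / union
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(d, labels)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class Dendrogram:
    """Rooted agglomerative tree with merge heights.

    ``linkage`` is a scipy linkage matrix over ``labels`` (sorted order as
    clustered); heights use the d/2 convention so that the cophenetic
    distance between two leaves equals the distance at which their
    clusters merged.
    """

    linkage: np.ndarray
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    def cophenetic(self) -> DistanceMatrix:
        """Leaf-to-leaf cophenetic distances implied by the tree."""
        coph = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(squareform(coph), list(self.labels))

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        h = self.linkage[:, 2]
        return bool(np.all(np.diff(h) >= -tol))


def upgma(D: DistanceMatrix) -> Dendrogram:
    """UPGMA (average linkage with cluster-size weighting).

    Deterministic under ties: entities are processed in sorted-label order
    so equal-distance merges resolve lexicographically.
    """
    if D.n < 2:
        raise ValueError("UPGMA needs at least two entities")
    order = np.argsort(np.asarray(D.labels, dtype=object))
    labels = [D.labels[i] for i in order]
    M = D.matrix[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(M, checks=False), method="average")
    return Dendrogram(Z, labels)


def to_newick(t: Dendrogram) -> str:
    """Serialize a dendrogram to newick; branch lengths are height
    differences under the d/2 height convention."""
    n = len(t.labels)
    heights = t.heights

    def node_height(idx: int) -> float:
        return 0.0 if idx < n else heights[idx - n]

    def min_label(idx: int) -> str:
        if idx < n:
            return str(t.labels[idx])
        a, b = int(t.linkage[idx - n, 0]), int(t.linkage[idx - n, 1])
        return min(min_label(a), min_label(b))

    def kids(idx: int):
        a, b = int(t.linkage[idx - n, 0]), int(t.linkage[idx - n, 1])
        return sorted((a, b), key=min_label)

    def render(idx: int, parent_h: float) -> str:
        bl = parent_h - node_height(idx)
        if idx < n:
            return f"{t.labels[idx]}:{_fmt(bl)}"
        h = node_height(idx)
        a, b = kids(idx)
        return f"({render(a, h)},{render(b, h)}):{_fmt(bl)}"

    root = n + len(heights) - 1
    h = node_height(root)
    a, b = kids(root)
    return f"({render(a, h)},{render(b, h)});"


def _fmt(x: float) -> str:
    return f"{x:.10g}"
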