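"""Shared-nearest-neighbor graph construction and community detection.

Cells are connected by the Jaccard similarity of their k-nearest-neighbor
sets (Euclidean distance on the clustering channels), weak edges are
pruned, and communities are found by resolution-scaled modularity
optimization (Leiden). Small communities — below a minimum cell count —
are unassigned and excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .events import EventTable
from .io import PanelConfig

__all__ = [
    "SNNGraph",
    "ClusterLabels",
    "knn_neighbors",
    "snn_jaccard",
    "cluster_graph",
    "filter_clusters",
]

DEFAULT_K = 20
DEFAULT_PRUNE = 1.0 / 15.0
DEFAULT_MIN_CELLS = 50
UNASSIGNED = -1


@dataclass
class SNNGraph:
    """Undirected SNN graph: kNN sets plus pruned Jaccard-weighted edges."""

    n_cells: int
    k: int
    neighbors: np.ndarray  # (n_cells, k) neighbor indices
    edge_u: np.ndarray
    edge_v: np.ndarray
    weights: np.ndarray  # Jaccard weights in (prune_threshold, 1]
    prune_threshold: float

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(
            n=self.n_cells,
            edges=np.column_stack([self.edge_u, self.edge_v]).tolist(),
        )
        g.es["weight"] = self.weights.tolist()
        return g

    def edge_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"u": self.edge_u, "v": self.edge_v, "weight": self.weights})


@dataclass
class ClusterLabels:
    """Per-cell community ids; ``-1`` marks unassigned cells."""

    labels: np.ndarray
    resolution: float
    seed: int
    min_cells: int = 0

    @property
    def n_clusters(self) -> int:
        return int((np.unique(self.labels) != UNASSIGNED).sum())

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels != UNASSIGNED], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def knn_from_matrix(X: np.ndarray, k: int) -> np.ndarray:
    """Exact k nearest neighbors (Euclidean), self excluded.

    Distance ties are broken toward the lower cell index; candidate
    fetching is widened until the decision boundary is unambiguous, so
    the result matches a brute-force all-pairs scan.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    n_fetch = min(n, k + 2)
    while True:
        nn = NearestNeighbors(n_neighbors=n_fetch, n_jobs=1).fit(X)
        dist, idx = nn.kneighbors(X)
        out = np.empty((n, k), dtype=np.int64)
        widen = False
        for i in range(n):
            keep = idx[i] != i
            d, j = dist[i][keep], idx[i][keep]
            if len(j) < k:
                widen = True
                break
            order = np.lexsort((j, d))
            d, j = d[order], j[order]
            # ambiguous if unfetched candidates could tie at the boundary
            if n_fetch < n and len(d) > k and d[k - 1] == d[-1]:
                widen = True
                break
            out[i] = j[:k]
        if not widen:
            return out
        n_fetch = min(n, n_fetch * 2)


def knn_neighbors(table: EventTable, panel: PanelConfig, k: int = DEFAULT_K) -> np.ndarray:
    """kNN sets on the panel's clustering channels."""
    return knn_from_matrix(panel.clustering_matrix(table), k)


def snn_jaccard(knn: np.ndarray, prune_threshold: float = DEFAULT_PRUNE) -> SNNGraph:
    """Jaccard-weighted shared-nearest-neighbor graph.

    ``weight(u, v) = |N(u) ∩ N(v)| / |N(u) ∪ N(v)|`` over the two kNN
    sets (self excluded); edges with weight <= ``prune_threshold`` are
    dropped. With equal set sizes the union is ``2k - |∩|``.
    """
    knn = np.asarray(knn)
    n, k = knn.shape
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k, dtype=np.float64), (rows, knn.ravel())), shape=(n, n)
    )
    inter = (adj @ adj.T).tocoo()
    upper = inter.row < inter.col
    u, v, shared = inter.row[upper], inter.col[upper], inter.data[upper]
    w = shared / (2 * k - shared)
    keep = w > prune_threshold
    return SNNGraph(
        n_cells=n,
        k=k,
        neighbors=knn,
        edge_u=u[keep].astype(np.int64),
        edge_v=v[keep].astype(np.int64),
        weights=w[keep],
        prune_threshold=prune_threshold,
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel assigned clusters 0..m-1 by descending size (ties: first member)."""
    out = np.full_like(labels, UNASSIGNED)
    ids = [c for c in np.unique(labels) if c != UNASSIGNED]
    first_member = {c: int(np.argmax(labels == c)) for c in ids}
    ids.sort(key=lambda c: (-(labels == c).sum(), first_member[c]))
    for new, old in enumerate(ids):
        out[labels == old] = new
    return out


def cluster_graph(graph: SNNGraph, resolution: float, seed: int = 0) -> ClusterLabels:
    """Leiden community detection with resolution-scaled modularity.

    Deterministic given ``seed``; clusters are relabeled by descending
    size.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if graph.n_cells == 0:
        raise ValueError("cannot cluster an empty graph")
    part = leidenalg.find_partition(
        graph.to_igraph(),
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = _relabel_by_size(np.asarray(part.membership, dtype=np.int64))
    return ClusterLabels(labels=labels, resolution=resolution, seed=seed)


def filter_clusters(labels: ClusterLabels, min_cells: int = DEFAULT_MIN_CELLS) -> ClusterLabels:
    """Unassign cells of clusters smaller than ``min_cells``.

    Clusters with exactly ``min_cells`` members are retained; surviving
    clusters are relabeled by descending size.
    """
    lab = labels.labels.copy()
    ids, counts = np.unique(lab[lab != UNASSIGNED], return_counts=True)
    for c, cnt in zip(ids, counts):
        if cnt < min_cells:
            lab[lab == c] = UNASSIGNED
    return replace(labels, labels=_relabel_by_size(lab), min_cells=min_cells)
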