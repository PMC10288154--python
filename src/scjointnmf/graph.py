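"""Feature–feature similarity graphs and their Laplacians.

The graph penalty tr(WᵀLW) couples the loadings of similar features.  For a
modality with M features observed on N cells, features are treated as points
in N-dimensional cell space and connected to their k nearest Euclidean
neighbors (computed from the raw counts — normalization would distort the
feature geometry).  The multiplicative W-update consumes the Laplacian
through its elementwise positive/negative split: for an unweighted graph,
[L]⁺ is the degree matrix and [L]⁻ the adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "FeatureGraph",
    "build_knn_feature_graph",
    "identity_graph",
    "split_laplacian",
    "load_edge_list",
    "write_edge_list",
    "graph_penalty",
]

GraphSource = Literal["knn_from_data", "identity", "user_supplied"]


@dataclass
class FeatureGraph:
    """Adjacency, Laplacian L = D − A, and the split L = [L]⁺ − [L]⁻."""

    adjacency: sp.csr_matrix
    degree: np.ndarray
    laplacian: sp.csr_matrix
    lap_pos: sp.csr_matrix
    lap_neg: sp.csr_matrix
    k: Optional[int] = None
    source: GraphSource = "knn_from_data"
    feature_ids: Optional[list[str]] = None

    @property
    def n_features(self) -> int:
        return self.adjacency.shape[0]


def split_laplacian(l) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Elementwise split of a square matrix into non-negative parts.

    Returns ``(lap_pos, lap_neg)`` with ``lap_pos - lap_neg == l`` exactly and
    disjoint supports.
    """
    l = sp.csr_matrix(l)
    if l.shape[0] != l.shape[1]:
        raise ValueError(f"Laplacian must be square, got {l.shape}")
    pos = l.copy()
    pos.data = np.maximum(l.data, 0.0)
    pos.eliminate_zeros()
    neg = l.copy()
    neg.data = np.maximum(-l.data, 0.0)
    neg.eliminate_zeros()
    return pos.tocsr(), neg.tocsr()


def _graph_from_adjacency(
    adjacency: sp.csr_matrix,
    k: Optional[int],
    source: GraphSource,
    feature_ids: Optional[Sequence[str]],
) -> FeatureGraph:
    adjacency = sp.csr_matrix(adjacency)
    degree = np.asarray(adjacency.sum(axis=1)).ravel()
    laplacian = (sp.diags(degree) - adjacency).tocsr()
    lap_pos, lap_neg = split_laplacian(laplacian)
    return FeatureGraph(
        adjacency=adjacency,
        degree=degree,
        laplacian=laplacian,
        lap_pos=lap_pos,
        lap_neg=lap_neg,
        k=k,
        source=source,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )


def _knn_indices(coords: np.ndarray, k: int, chunk: int = 1024) -> np.ndarray:
    """Indices of the k nearest neighbors (self excluded) of every row.

    Squared Euclidean distances are computed blockwise with BLAS; ties are
    broken deterministically by feature index via a (distance, index) lexsort
    over an argpartition candidate set.
    """
    m = coords.shape[0]
    sq = np.einsum("ij,ij->i", coords, coords)
    out = np.empty((m, k), dtype=np.int64)
    # candidate pool comfortably larger than k so boundary ties cannot bite
    n_cand = min(m, max(4 * k + 8, k + 16))
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        block = coords[start:stop]
        d = sq[start:stop, None] + sq[None, :] - 2.0 * (block @ coords.T)
        np.maximum(d, 0.0, out=d)
        rows = np.arange(start, stop)
        d[np.arange(stop - start), rows] = -1.0  # pin self first
        if n_cand < m:
            cand = np.argpartition(d, n_cand - 1, axis=1)[:, :n_cand]
        else:
            cand = np.broadcast_to(np.arange(m), (stop - start, m))
        cand_d = np.take_along_axis(d, cand, axis=1)
        # stable sort of (distance, index): sort candidates by index first
        idx_order = np.argsort(cand, axis=1, kind="stable")
        cand = np.take_along_axis(cand, idx_order, axis=1)
        cand_d = np.take_along_axis(cand_d, idx_order, axis=1)
        dist_order = np.argsort(cand_d, axis=1, kind="stable")
        ranked = np.take_along_axis(cand, dist_order, axis=1)
        out[start:stop] = ranked[:, 1 : k + 1]  # drop self (distance −1)
    return out


def build_knn_feature_graph(x, k: int = 10) -> FeatureGraph:
    """Union-symmetrized, unweighted k-nearest-neighbor feature graph.

    Parameters
    ----------
    x : CountMatrix
        Raw counts; features are the graph's points, cells the coordinates.
    k : int
        Neighbors per feature before symmetrization (default 10).
    """
    if getattr(x, "flavor", "raw") != "raw":
        raise ValueError("feature graphs are built from raw counts")
    values = x.values if hasattr(x, "values") else sp.csr_matrix(x)
    m, n = values.shape
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k >= m:
        raise ValueError(f"k={k} requires more than {m} features")
    if n >= m:
        raise ValueError(
            f"KNN feature graphs from data need more features than cells "
            f"(M={m}, N={n}); supply an external graph instead"
        )
    coords = np.asarray(values.todense(), dtype=np.float64)
    nbrs = _knn_indices(coords, k)
    rows = np.repeat(np.arange(m), k)
    directed = sp.csr_matrix(
        (np.ones(m * k), (rows, nbrs.ravel())), shape=(m, m)
    )
    adjacency = directed.maximum(directed.T)  # union symmetrization
    adjacency.data[:] = 1.0
    adjacency.setdiag(0)
    adjacency.eliminate_zeros()
    return _graph_from_adjacency(
        adjacency, k, "knn_from_data", getattr(x, "feature_ids", None)
    )


def identity_graph(m: int) -> FeatureGraph:
    """Identity Laplacian: the graph penalty degenerates to ½λ‖W‖²_F."""
    if m < 1:
        raise ValueError("m must be positive")
    eye = sp.identity(m, format="csr")
    zero = sp.csr_matrix((m, m))
    return FeatureGraph(
        adjacency=zero,
        degree=np.ones(m),
        laplacian=eye.copy(),
        lap_pos=eye.copy(),
        lap_neg=zero,
        k=None,
        source="identity",
    )


def load_edge_list(path, feature_ids: Sequence[str]) -> FeatureGraph:
    """Read a user-supplied graph from ``id_a <tab> id_b [<tab> weight]`` lines.

    Edges are symmetrized; weighted graphs are allowed (degrees become
    weighted degrees).  Ids must match ``feature_ids``.
    """
    index = {f: i for i, f in enumerate(feature_ids)}
    m = len(feature_ids)
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected at least two columns")
            a, b = parts[0], parts[1]
            w = float(parts[2]) if len(parts) > 2 else 1.0
            if a not in index or b not in index:
                missing = a if a not in index else b
                raise ValueError(f"{path}:{ln}: unknown feature id {missing!r}")
            if w < 0:
                raise ValueError(f"{path}:{ln}: negative edge weight")
            i, j = index[a], index[b]
            if i == j:
                continue
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
    adjacency = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    adjacency.sum_duplicates()
    # duplicate edge lines collapse to the maximum weight
    adjacency = adjacency.maximum(adjacency.T)
    return _graph_from_adjacency(adjacency, None, "user_supplied", feature_ids)


def write_edge_list(graph: FeatureGraph, path) -> None:
    ids = graph.feature_ids or [str(i) for i in range(graph.n_features)]
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{ids[i]}\t{ids[j]}\t{w:g}\n")


def graph_penalty(w: np.ndarray, graph: FeatureGraph, lam: float) -> float:
    """½·λ·tr(Wᵀ L W); with the identity Laplacian this is ½·λ·‖W‖²_F."""
    if lam == 0:
        return 0.0
    return 0.5 * lam * float(np.sum(w * (graph.laplacian @ w)))
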