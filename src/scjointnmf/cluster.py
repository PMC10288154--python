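"""Clustering cells from the fitted shared factor matrix H, plus evaluation.

Cells are the columns of H, treated as D-dimensional points and clustered
with restarted k-means.  Diagnostics over a range of k (silhouette width,
within-cluster sum of squares, gap statistic) support choosing the cluster
count on unlabeled data; ARI and AMI score a partition against reference
labels with chance correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    silhouette_score,
)

from .io import write_labels  # noqa: F401  (re-exported convenience)

__all__ = [
    "ClusterResult",
    "kmeans_cluster",
    "cluster_diagnostics",
    "adjusted_rand_index",
    "adjusted_mutual_info",
]


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    inertia: float
    seed: int
    restarts: int


def _cell_points(model_or_h) -> np.ndarray:
    """(N, D) cell coordinates from H (D×N), a FactorModel, or an estimator."""
    h = getattr(model_or_h, "H_", None)
    if h is None:
        h = getattr(model_or_h, "H", None)
    if h is None:
        h = model_or_h
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2:
        raise ValueError("H must be a 2-D matrix")
    return h.T


def kmeans_cluster(model, k: int, seed: int = 0, restarts: int = 25) -> ClusterResult:
    """Restarted k-means on the columns of H; deterministic given the seed."""
    points = _cell_points(model)
    n = points.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} cells")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(points)
    return ClusterResult(
        labels=labels.astype(int),
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def _wss_monotone_kmeans(points, k, seed, restarts, prev_centers):
    """Best of seeded restarts and a warm start split from the previous k.

    Warm-starting from the (k−1)-solution's centers plus the point farthest
    from its center guarantees WSS(k) ≤ WSS(k−1).
    """
    best = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(points)
    if prev_centers is not None and prev_centers.shape[0] == k - 1:
        d2 = ((points[:, None, :] - prev_centers[None, :, :]) ** 2).sum(axis=-1)
        resid = d2.min(axis=1)
        init = np.vstack([prev_centers, points[int(np.argmax(resid))]])
        warm = KMeans(n_clusters=k, init=init, n_init=1).fit(points)
        if warm.inertia_ < best.inertia_:
            best = warm
    return best


def cluster_diagnostics(
    model,
    k_range: Sequence[int] = tuple(range(2, 11)),
    seed: int = 0,
    restarts: int = 25,
    gap_b: int = 50,
) -> pd.DataFrame:
    """Cluster-count diagnostics on H: silhouette, WSS, and gap statistic.

    The gap statistic compares log(WSS) against ``gap_b`` seeded reference
    datasets drawn uniformly over the bounding box of the cell points;
    ``gap_se`` is the usual sd·sqrt(1 + 1/B) standard error.
    """
    points = _cell_points(model)
    n = points.shape[0]
    if np.allclose(points, points[0]):
        raise ValueError("degenerate H: all cells identical")
    k_range = [int(k) for k in k_range]
    if any(not 2 <= k <= n - 1 for k in k_range):
        raise ValueError(f"k_range must lie within 2…{n - 1}")

    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)
    refs = [rng.uniform(lo, hi, size=points.shape) for _ in range(gap_b)]

    rows = []
    prev_centers = None
    for k in sorted(k_range):
        km = _wss_monotone_kmeans(points, k, seed, restarts, prev_centers)
        prev_centers = km.cluster_centers_
        sil = float(silhouette_score(points, km.labels_))
        log_ref = np.array(
            [
                np.log(KMeans(n_clusters=k, n_init=5, random_state=seed).fit(r).inertia_)
                for r in refs
            ]
        )
        gap = float(log_ref.mean() - np.log(km.inertia_))
        gap_se = float(log_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / gap_b))
        rows.append(
            {"k": k, "silhouette": sil, "wss": float(km.inertia_), "gap": gap, "gap_se": gap_se}
        )
    return pd.DataFrame(rows)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape[0]} vs {b.shape[0]}")
    if a.size < 2:
        raise ValueError("need at least two labels")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Chance-corrected under the hypergeometric model; 1 iff the partitions are
    identical up to relabeling, ≈0 for independent partitions.
    """
    a, b = _check_pair(a, b)
    return float(adjusted_rand_score(a, b))


def adjusted_mutual_info(a, b) -> float:
    """Adjusted mutual information with max-entropy normalization."""
    a, b = _check_pair(a, b)
    return float(adjusted_mutual_info_score(a, b, average_method="max"))
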