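"""Choosing the latent dimension D and the regularization weights.

D is chosen visually from an elbow plot: for every candidate D the model is
initialized with NNDSVD and run for a small fixed budget (100 iterations for
the ridge-on-H mode, 1 for the unit-norm mode, whose per-iteration cost is
higher and whose early loss already separates candidates), and the final
objective is plotted against D.  The bend of the curve is the recommended D.
An optional max-distance-to-chord heuristic annotates a suggestion but never
auto-selects.

The λ defaults encode the values found to work well for paired
scRNA-seq/scATAC-seq data; a generic grid runner is provided for
dataset-specific tuning when ground-truth labels are available.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import adjusted_rand_index, kmeans_cluster
from .initialization import InitConfig
from .nmf import FitConfig, JointGraphNMF

__all__ = [
    "ElbowScan",
    "factor_elbow_scan",
    "suggest_elbow",
    "default_lambdas",
    "lambda_grid_search",
]

#: fixed iteration budget of the elbow scan, per constraint mode
SCAN_ITERS = {"sparsity_H": 100, "l2norm_H": 1}

#: recommended regularization bundles for paired RNA/ATAC data
DEFAULT_LAMBDA_W = {
    "sparsity_H": {"rna": 10.0, "atac": 50.0},
    "l2norm_H": {"rna": 3.0, "atac": 15.0},
}
DEFAULT_LAMBDA_H = {"sparsity_H": 500.0, "l2norm_H": 0.0}


@dataclass
class ElbowScan:
    d_values: list[int]
    losses: list[float]
    iters_per_candidate: int
    constraint: str
    suggestion: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.d_values) != len(self.losses):
            raise ValueError("d_values and losses lengths differ")
        if any(b <= a for a, b in zip(self.d_values, self.d_values[1:])):
            raise ValueError("d_values must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"D": self.d_values, "loss": self.losses})

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.d_values, self.losses, marker="o")
        if self.suggestion is not None:
            ax.axvline(self.suggestion, ls="--", color="grey")
        ax.set_xlabel("number of latent factors D")
        ax.set_ylabel("objective after fixed budget")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def factor_elbow_scan(
    data,
    graphs=None,
    d_values: Sequence[int] = tuple(range(2, 21)),
    constraint: str = "sparsity_H",
    lambda_w=None,
    lambda_h: float = 0.0,
    divergence: str = "poisson_kl",
    seed: int = 0,
    annotate: bool = True,
) -> ElbowScan:
    """Objective-vs-D table under a fixed small iteration budget.

    Each candidate is fit independently from a fresh NNDSVD initialization
    with early stopping disabled, so the scan is deterministic and candidates
    do not leak state into each other.
    """
    d_values = sorted(int(d) for d in d_values)
    iters = SCAN_ITERS[constraint]
    losses = []
    for d in d_values:
        est = JointGraphNMF(
            n_components=d,
            constraint=constraint,
            divergence=divergence,
            lambda_w=lambda_w,
            lambda_h=lambda_h,
            init="nndsvd",
            max_iter=iters,
            tol=1e-300,  # no early stop: run the full budget
            loss_every=iters,
            random_state=seed,
        )
        est.fit(data, graphs=graphs)
        losses.append(float(est.loss_trace_[-1, 1]))
    scan = ElbowScan(d_values, losses, iters, constraint)
    if annotate and len(d_values) >= 3:
        scan.suggestion = suggest_elbow(scan)
    return scan


def suggest_elbow(scan: ElbowScan) -> int:
    """Kneedle-style annotation: the D farthest below the first-to-last chord."""
    d = np.asarray(scan.d_values, dtype=float)
    y = np.asarray(scan.losses, dtype=float)
    span = y[0] - y[-1]
    if span == 0:
        return scan.d_values[0]
    dn = (d - d[0]) / (d[-1] - d[0])
    yn = (y - y[-1]) / span
    dist = (1.0 - dn) - yn  # height of the chord minus the curve
    return int(scan.d_values[int(np.argmax(dist))])


def default_lambdas(
    modality_kinds: Sequence[str], constraint: str = "sparsity_H"
) -> tuple[list[float], float]:
    """Recommended (λ_W per modality, λ_H) for the given modality kinds.

    Ridge-on-H mode: λ_W = 10 (RNA) / 50 (ATAC), λ_H = 500.  Unit-norm mode:
    λ_W = 3 (RNA) / 15 (ATAC), λ_H unused (0).  Unknown kinds fall back to the
    RNA defaults with a warning.
    """
    if constraint not in DEFAULT_LAMBDA_W:
        raise ValueError(f"unknown constraint {constraint!r}")
    table = DEFAULT_LAMBDA_W[constraint]
    lam_w = []
    for kind in modality_kinds:
        kind = kind.lower()
        if kind not in table:
            warnings.warn(
                f"no default λ_W for modality kind {kind!r}; using the RNA value"
            )
            kind = "rna"
        lam_w.append(table[kind])
    return lam_w, DEFAULT_LAMBDA_H[constraint]


def lambda_grid_search(
    data,
    graphs,
    lambda_w_grids: Sequence[Sequence[float]],
    lambda_h_grid: Sequence[float],
    d: int = 10,
    constraint: str = "sparsity_H",
    divergence: str = "poisson_kl",
    n_clusters: Optional[int] = None,
    labels=None,
    fit_config: Optional[FitConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid runner over (λ_Wᵛ…, λ_H); reports post-hoc ARI when labels given.

    Returns one row per combination with the final objective and, if reference
    labels are supplied, the k-means ARI against them.
    """
    fit_config = fit_config or FitConfig(max_iter=200, loss_every=10)
    labels = np.asarray(labels) if labels is not None else None
    if labels is not None and n_clusters is None:
        n_clusters = len(np.unique(labels))
    rows = []
    for combo in itertools.product(*lambda_w_grids, lambda_h_grid):
        lam_w, lam_h = list(combo[:-1]), combo[-1]
        est = JointGraphNMF(
            n_components=d,
            constraint=constraint,
            divergence=divergence,
            lambda_w=lam_w,
            lambda_h=lam_h,
            max_iter=fit_config.max_iter,
            tol=fit_config.tol,
            loss_every=fit_config.loss_every,
            random_state=seed,
        )
        est.fit(data, graphs=graphs)
        row = {f"lambda_w_{v}": l for v, l in enumerate(lam_w)}
        row["lambda_h"] = lam_h
        row["loss"] = float(est.loss_trace_[-1, 1])
        row["converged"] = est.converged_
        if labels is not None:
            res = kmeans_cluster(est.H_, k=n_clusters, seed=seed)
            row["ari"] = adjusted_rand_index(labels, res.labels)
        rows.append(row)
    return pd.DataFrame(rows)
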