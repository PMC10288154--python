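"""Joint graph-regularized NMF with a shared cell-loading matrix.

Given V modalities of median-library-size-normalized count matrices
X¹…Xᵛ (features × cells, same ordered cells), the model factorizes each
Xᵛ ≈ Wᵛ H with one shared D×N cell matrix H and per-modality Mᵛ×D feature
matrices Wᵛ, minimizing

    Σ_v D(Xᵛ ‖ Wᵛ H)  +  Σ_v ½ λ_Wᵛ tr(Wᵛᵀ Lᵛ Wᵛ)  +  penalty(H)

where D is the Poisson KL divergence (or squared Frobenius norm), Lᵛ a
feature-feature graph Laplacian, and penalty(H) either the ridge
½ λ_H ‖H‖²_F ("sparsity_H") or the constraint that every column of H has unit
L2 norm ("l2norm_H"), enforced through a tangent-corrected multiplicative
update.  Optimization is by multiplicative updates from a strictly positive
initialization; with L = I the graph penalty reduces exactly to ½ λ ‖W‖²_F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from . import _updates as up
from .graph import FeatureGraph, graph_penalty, identity_graph
from .initialization import InitConfig, initialize_factors
from .io import CountMatrix, MultiModalDataset

__all__ = [
    "FitConfig",
    "FactorModel",
    "JointGraphNMF",
    "kl_objective",
    "frobenius_objective",
    "fit_factorization",
]

CONSTRAINTS = ("sparsity_H", "l2norm_H")
DIVERGENCES = ("poisson_kl", "frobenius")


@dataclass
class FitConfig:
    """Solver settings.  Defaults: at most 10,000 iterations, stopping when
    the relative change of the objective drops below 1e-6."""

    max_iter: int = 10_000
    tol: float = 1e-6
    eps: float = 1e-16
    loss_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0 or self.eps <= 0:
            raise ValueError("tol and eps must be positive")
        if self.loss_every < 1:
            raise ValueError("loss_every must be >= 1")


@dataclass
class FactorModel:
    """Fitted (or initial) factorization state."""

    W: list
    H: np.ndarray
    lambda_W: list
    lambda_H: float
    constraint: str = "sparsity_H"
    divergence: str = "poisson_kl"
    loss_trace: list = field(default_factory=list)
    converged: bool = False
    iterations_run: int = 0
    seed: Optional[int] = None
    feature_ids: Optional[list] = None
    cell_ids: Optional[list] = None

    @property
    def n_components(self) -> int:
        return self.H.shape[0]

    def save(self, outdir) -> None:
        """Write W^v/H as delimited matrices, the loss trace as CSV, and a
        JSON sidecar with hyperparameters and convergence status."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cell_ids = self.cell_ids or [f"cell{j}" for j in range(self.H.shape[1])]
        comp = [f"factor{d}" for d in range(self.n_components)]
        pd.DataFrame(self.H, index=comp, columns=cell_ids).to_csv(outdir / "H.tsv", sep="\t")
        for v, w in enumerate(self.W):
            fids = (
                self.feature_ids[v]
                if self.feature_ids is not None
                else [f"f{v}_{i}" for i in range(w.shape[0])]
            )
            pd.DataFrame(w, index=fids, columns=comp).to_csv(
                outdir / f"W{v}.tsv", sep="\t"
            )
        pd.DataFrame(self.loss_trace, columns=["iteration", "loss"]).to_csv(
            outdir / "loss_trace.csv", index=False
        )
        meta = {
            "lambda_W": [float(l) for l in self.lambda_W],
            "lambda_H": float(self.lambda_H),
            "constraint": self.constraint,
            "divergence": self.divergence,
            "converged": bool(self.converged),
            "iterations_run": int(self.iterations_run),
            "seed": self.seed,
            "n_modalities": len(self.W),
            "n_components": self.n_components,
        }
        (outdir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir) -> "FactorModel":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        h_df = pd.read_csv(outdir / "H.tsv", sep="\t", index_col=0)
        w_list, fids = [], []
        for v in range(meta["n_modalities"]):
            w_df = pd.read_csv(outdir / f"W{v}.tsv", sep="\t", index_col=0)
            w_list.append(w_df.to_numpy())
            fids.append([str(i) for i in w_df.index])
        trace = pd.read_csv(outdir / "loss_trace.csv").to_numpy().tolist()
        return cls(
            W=w_list,
            H=h_df.to_numpy(),
            lambda_W=meta["lambda_W"],
            lambda_H=meta["lambda_H"],
            constraint=meta["constraint"],
            divergence=meta["divergence"],
            loss_trace=[(int(i), float(l)) for i, l in trace],
            converged=meta["converged"],
            iterations_run=meta["iterations_run"],
            seed=meta["seed"],
            feature_ids=fids,
            cell_ids=[str(c) for c in h_df.columns],
        )


def _as_workspaces(data) -> tuple[list[up.ModalityWorkspace], Optional[list], Optional[list]]:
    if isinstance(data, MultiModalDataset):
        mats = [cm.values for cm in data.modalities]
        fids = [cm.feature_ids for cm in data.modalities]
        cids = data.cell_ids
    else:
        mats = [sp.csr_matrix(m) for m in data]
        fids, cids = None, None
    n = mats[0].shape[1]
    for m in mats:
        if m.shape[1] != n:
            raise ValueError("modalities disagree on the number of cells")
        if m.data.size and m.data.min() < 0:
            raise ValueError("data matrices must be non-negative")
    return [up.ModalityWorkspace(m) for m in mats], fids, cids


def _resolve_graphs(graphs, workspaces, fids) -> list[FeatureGraph]:
    if graphs is None:
        return [identity_graph(ws.shape[0]) for ws in workspaces]
    if len(graphs) != len(workspaces):
        raise ValueError("one graph per modality required")
    for v, (g, ws) in enumerate(zip(graphs, workspaces)):
        if g.n_features != ws.shape[0]:
            raise ValueError(
                f"graph {v} has {g.n_features} nodes but modality {v} has "
                f"{ws.shape[0]} features"
            )
        if fids is not None and g.feature_ids is not None and list(g.feature_ids) != list(fids[v]):
            raise ValueError(f"graph {v} feature ids do not match the data")
    return list(graphs)


def _objective(
    workspaces, w_list, h, graphs, lambda_w, lambda_h, constraint, divergence
) -> float:
    term = (
        up.kl_objective_terms
        if divergence == "poisson_kl"
        else up.frobenius_objective_terms
    )
    total = 0.0
    for ws, w, g, lam in zip(workspaces, w_list, graphs, lambda_w):
        total += term(ws, w, h)
        total += graph_penalty(w, g, lam)
    if constraint == "sparsity_H":
        total += 0.5 * lambda_h * float(np.sum(h * h))
    return total


def kl_objective(data, model: FactorModel, graphs=None) -> float:
    """Full KL objective: data-fit divergence plus graph and H penalties."""
    workspaces, fids, _ = _as_workspaces(data)
    graphs = _resolve_graphs(graphs, workspaces, fids)
    return _objective(
        workspaces, model.W, model.H, graphs, model.lambda_W, model.lambda_H,
        model.constraint, "poisson_kl",
    )


def frobenius_objective(data, model: FactorModel, graphs=None) -> float:
    """Full Frobenius objective with the same penalty structure."""
    workspaces, fids, _ = _as_workspaces(data)
    graphs = _resolve_graphs(graphs, workspaces, fids)
    return _objective(
        workspaces, model.W, model.H, graphs, model.lambda_W, model.lambda_H,
        model.constraint, "frobenius",
    )


class JointGraphNMF(BaseEstimator, TransformerMixin):
    """Joint multi-modality NMF with graph-regularized feature loadings.

    Parameters
    ----------
    n_components : int
        Number of latent factors D (must satisfy D < min(Mᵛ, N)).
    constraint : {"sparsity_H", "l2norm_H"}
        Ridge penalty on H, or unit L2 norm per H column.
    divergence : {"poisson_kl", "frobenius"}
        Data-fit term; Poisson KL is the natural choice for counts.
    lambda_w : sequence of float or None
        Graph-regularization weight per modality (None → 0 everywhere; see
        :func:`scjointnmf.model_selection.default_lambdas` for the
        recommended RNA/ATAC bundles).
    lambda_h : float or None
        Ridge weight on H (ignored under "l2norm_H"; None → 0).
    init : {"nndsvd", "random"}
        NNDSVD is deterministic and markedly more accurate in practice.
    max_iter, tol, eps, loss_every
        Solver settings; convergence when the relative objective change
        between consecutive evaluations falls below ``tol``.
    random_state : int
        Seed for the random initialization (NNDSVD ignores it).

    Attributes
    ----------
    W_ : list of (Mᵛ, D) ndarrays
    H_ : (D, N) ndarray — shared cell loadings.
    loss_trace_ : (T, 2) ndarray of (iteration, objective).
    n_iter_ : int
    converged_ : bool
    model_ : FactorModel

    Examples
    --------
    >>> est = JointGraphNMF(n_components=3, lambda_w=[1.0], lambda_h=10.0)
    >>> embedding = est.fit_transform([x_normalized], graphs=[graph])
    """

    def __init__(
        self,
        n_components: int = 10,
        constraint: str = "sparsity_H",
        divergence: str = "poisson_kl",
        lambda_w=None,
        lambda_h=None,
        init: str = "nndsvd",
        max_iter: int = 10_000,
        tol: float = 1e-6,
        eps: float = 1e-16,
        loss_every: int = 1,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.constraint = constraint
        self.divergence = divergence
        self.lambda_w = lambda_w
        self.lambda_h = lambda_h
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.loss_every = loss_every
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate(self, n_modalities: int) -> tuple[list, float]:
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"constraint must be one of {CONSTRAINTS}")
        if self.divergence not in DIVERGENCES:
            raise ValueError(f"divergence must be one of {DIVERGENCES}")
        if self.lambda_w is None:
            lam_w = [0.0] * n_modalities
        elif np.isscalar(self.lambda_w):
            lam_w = [float(self.lambda_w)] * n_modalities
        else:
            lam_w = [float(l) for l in self.lambda_w]
            if len(lam_w) != n_modalities:
                raise ValueError("lambda_w length must equal the modality count")
        if any(l < 0 for l in lam_w):
            raise ValueError("lambda_w must be non-negative")
        lam_h = 0.0 if self.lambda_h is None else float(self.lambda_h)
        if lam_h < 0:
            raise ValueError("lambda_h must be non-negative")
        return lam_w, lam_h

    def _init_factors(self, data, workspaces):
        if isinstance(data, MultiModalDataset):
            cfg = InitConfig(method=self.init, d=self.n_components, seed=self.random_state)
            return initialize_factors(data, cfg)
        # bare matrices: wrap minimally (assumed already normalized)
        cms = []
        n = workspaces[0].shape[1]
        cells = [f"cell{j}" for j in range(n)]
        for v, ws in enumerate(workspaces):
            cms.append(
                CountMatrix(
                    ws.x,
                    [f"m{v}_f{i}" for i in range(ws.shape[0])],
                    cells,
                    modality_name=f"modality{v}",
                    flavor="normalized",
                )
            )
        cfg = InitConfig(method=self.init, d=self.n_components, seed=self.random_state)
        return initialize_factors(MultiModalDataset(cms), cfg)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None, graphs=None, W_init=None, H_init=None):
        """Fit the factorization.

        Parameters
        ----------
        X : MultiModalDataset or sequence of (Mᵛ, N) matrices
            Normalized data, one matrix per modality, columns = cells.
        graphs : sequence of FeatureGraph or None
            One Laplacian per modality; None → identity Laplacians (the graph
            penalty becomes a plain ridge on each Wᵛ).
        W_init, H_init : optional explicit strictly positive starting factors.
        """
        workspaces, fids, cids = _as_workspaces(X)
        lam_w, lam_h = self._validate(len(workspaces))
        graphs = _resolve_graphs(graphs, workspaces, fids)
        cfg = FitConfig(
            max_iter=self.max_iter,
            tol=self.tol,
            eps=self.eps,
            loss_every=self.loss_every,
            seed=self.random_state,
        )

        if W_init is not None and H_init is not None:
            w_list = [np.array(w, dtype=np.float64) for w in W_init]
            h = np.array(H_init, dtype=np.float64)
        elif W_init is None and H_init is None:
            w_list, h = self._init_factors(X, workspaces)
        else:
            raise ValueError("supply both W_init and H_init or neither")
        for w in w_list:
            if w.min() <= 0:
                raise ValueError("initial W must be strictly positive")
        if h.min() <= 0:
            raise ValueError("initial H must be strictly positive")
        if self.constraint == "l2norm_H":
            h = h / np.linalg.norm(h, axis=0)

        kl = self.divergence == "poisson_kl"
        loss = _objective(
            workspaces, w_list, h, graphs, lam_w, lam_h, self.constraint, self.divergence
        )
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite objective at initialization")
        trace = [(0, loss)]
        prev = loss
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            for v, ws in enumerate(workspaces):
                if kl:
                    w_list[v] = up.update_w_kl(ws, w_list[v], h, lam_w[v], graphs[v], cfg.eps)
                else:
                    w_list[v] = up.update_w_frobenius(ws, w_list[v], h, lam_w[v], graphs[v], cfg.eps)
            if kl:
                if self.constraint == "sparsity_H":
                    h = up.update_h_sparsity(workspaces, w_list, h, lam_h, cfg.eps)
                else:
                    h = up.update_h_l2norm(workspaces, w_list, h, cfg.eps)
            else:
                h = up.update_h_frobenius(
                    workspaces, w_list, h, lam_h, cfg.eps, self.constraint
                )
            if it % cfg.loss_every == 0 or it == cfg.max_iter:
                loss = _objective(
                    workspaces, w_list, h, graphs, lam_w, lam_h,
                    self.constraint, self.divergence,
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite objective at iteration {it}")
                trace.append((it, loss))
                rel = abs(prev - loss) / abs(prev) if prev != 0 else 0.0
                prev = loss
                if rel < cfg.tol:
                    converged = True
                    break

        self.W_ = w_list
        self.H_ = h
        self.loss_trace_ = np.array(trace, dtype=np.float64)
        self.n_iter_ = it
        self.converged_ = converged
        self.lambda_w_ = lam_w
        self.lambda_h_ = lam_h
        self.model_ = FactorModel(
            W=w_list,
            H=h,
            lambda_W=lam_w,
            lambda_H=lam_h,
            constraint=self.constraint,
            divergence=self.divergence,
            loss_trace=[(int(i), float(l)) for i, l in trace],
            converged=converged,
            iterations_run=it,
            seed=self.random_state,
            feature_ids=fids,
            cell_ids=cids,
        )
        return self

    def transform(self, X=None):
        """Cell embedding: the columns of the shared H as (N, D) rows."""
        if not hasattr(self, "H_"):
            raise RuntimeError("estimator is not fitted")
        return self.H_.T.copy()

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)

    def objective(self, X, graphs=None) -> float:
        """Objective value of the fitted factors on data X."""
        if not hasattr(self, "H_"):
            raise RuntimeError("estimator is not fitted")
        fn = kl_objective if self.divergence == "poisson_kl" else frobenius_objective
        return fn(X, self.model_, graphs)


def fit_factorization(
    data,
    graphs=None,
    init: Optional[InitConfig] = None,
    config: Optional[FitConfig] = None,
    constraint: str = "sparsity_H",
    divergence: str = "poisson_kl",
    lambda_w=None,
    lambda_h: float = 0.0,
) -> FactorModel:
    """Functional wrapper: initialize, fit, and return the FactorModel."""
    init = init or InitConfig()
    config = config or FitConfig()
    est = JointGraphNMF(
        n_components=init.d,
        constraint=constraint,
        divergence=divergence,
        lambda_w=lambda_w,
        lambda_h=lambda_h,
        init=init.method,
        max_iter=config.max_iter,
        tol=config.tol,
        eps=config.eps,
        loss_every=config.loss_every,
        random_state=init.seed,
    )
    est.fit(data, graphs=graphs)
    return est.model_
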