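"""Objectives and multiplicative-update steps for the joint factorization.

All heavy terms exploit structure instead of materializing M×N dense
intermediates on large problems:

* ``X ⊘ (WH)`` is evaluated only on X's nonzero support (the ratio is zero
  elsewhere, and only products against it are ever needed);
* ``1_{M×N} Hᵀ`` collapses to a row of H's row-sums broadcast over features;
* ``Wᵀ 1_{M×N}`` collapses to W's column-sums broadcast over cells;
* ``Σ_ij (WH)_ij`` is the inner product of W's column sums with H's row sums.

The numerical floor ``eps`` is added to MU denominators only — never to
numerators and never inside logarithms — so fixed points are unbiased.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ModalityWorkspace",
    "kl_objective_terms",
    "frobenius_objective_terms",
    "update_w_kl",
    "update_h_sparsity",
    "update_h_l2norm",
    "update_w_frobenius",
    "update_h_frobenius",
]

# below this element count a dense W @ H product is cheaper than gathering
_DENSE_LIMIT = 40_000_000
_SUPPORT_CHUNK = 2_000_000


class ModalityWorkspace:
    """Precomputed sparse structure of one modality's data matrix."""

    def __init__(self, x):
        x = sp.csr_matrix(x).astype(np.float64)
        x.sum_duplicates()
        x.eliminate_zeros()
        self.x = x
        self.shape = x.shape
        coo = x.tocoo()
        self.rows = coo.row.astype(np.int64)
        self.cols = coo.col.astype(np.int64)
        self.data = x.data
        self.total = float(x.sum())
        # x·log(x) over the support, a constant of the KL objective
        self.xlogx = float(np.dot(self.data, np.log(self.data)))

    def wh_on_support(self, w: np.ndarray, h: np.ndarray) -> np.ndarray:
        """(WH)_ij at every nonzero position of X."""
        m, n = self.shape
        if m * n <= _DENSE_LIMIT:
            return (w @ h)[self.rows, self.cols]
        out = np.empty_like(self.data)
        for s in range(0, self.data.size, _SUPPORT_CHUNK):
            e = min(s + _SUPPORT_CHUNK, self.data.size)
            out[s:e] = np.einsum(
                "ij,ij->i", w[self.rows[s:e]], h[:, self.cols[s:e]].T
            )
        return out

    def ratio(self, w: np.ndarray, h: np.ndarray) -> sp.csr_matrix:
        """X ⊘ (WH) restricted to X's support, as a CSR matrix."""
        wh = self.wh_on_support(w, h)
        if wh.size and wh.min() <= 0.0:
            raise FloatingPointError(
                "(WH)_ij = 0 at a position where x_ij > 0: KL divergence "
                "is infinite (factors must stay strictly positive)"
            )
        r = self.x.copy()
        r.data = self.data / wh
        return r


def _sym_dot(mat: sp.spmatrix, w: np.ndarray) -> np.ndarray:
    """(M + Mᵀ) W for a sparse square matrix M."""
    return mat @ w + mat.T @ w


def kl_objective_terms(ws: ModalityWorkspace, w: np.ndarray, h: np.ndarray) -> float:
    """Poisson KL divergence Σ_ij [x log(x/(WH)) − x + (WH)] for one modality.

    Uses the convention 0·log 0 = 0; Σ(WH) is computed from factor sums
    without forming WH.
    """
    wh = ws.wh_on_support(w, h)
    if wh.size and wh.min() <= 0.0:
        raise FloatingPointError("(WH) vanishes on the support of X")
    cross = float(np.dot(ws.data, np.log(wh)))
    sum_wh = float(np.dot(w.sum(axis=0), h.sum(axis=1)))
    return ws.xlogx - cross - ws.total + sum_wh


def frobenius_objective_terms(
    ws: ModalityWorkspace, w: np.ndarray, h: np.ndarray
) -> float:
    """‖X − WH‖²_F for one modality, without materializing WH."""
    wh = ws.wh_on_support(w, h)
    x_sq = float(np.dot(ws.data, ws.data))
    cross = float(np.dot(ws.data, wh))
    wtw = w.T @ w
    hht = h @ h.T
    wh_sq = float(np.sum(wtw * hht))
    return x_sq - 2.0 * cross + wh_sq


def update_w_kl(
    ws: ModalityWorkspace,
    w: np.ndarray,
    h: np.ndarray,
    lam_w: float,
    graph,
    eps: float,
) -> np.ndarray:
    """One multiplicative step of the graph-regularized KL W-update.

    W ← W ⊙ [(X⊘(WH))Hᵀ + ½λ([L]⁻W + [L]⁻ᵀW)]
          ⊘ [1Hᵀ + ½λ([L]⁺W + [L]⁺ᵀW) + eps]
    """
    r = ws.ratio(w, h)
    numer = r @ h.T
    h_rowsum = h.sum(axis=1)
    if lam_w != 0.0:
        numer += 0.5 * lam_w * _sym_dot(graph.lap_neg, w)
        denom = 0.5 * lam_w * _sym_dot(graph.lap_pos, w)
        denom += h_rowsum[None, :]
        denom += eps
    else:
        denom = h_rowsum[None, :] + eps
    return w * numer / denom


def update_h_sparsity(
    workspaces: list[ModalityWorkspace],
    w_list: list[np.ndarray],
    h: np.ndarray,
    lam_h: float,
    eps: float,
) -> np.ndarray:
    """H ← H ⊙ [Σ_v Wᵀ(X⊘(WH))] ⊘ [Σ_v Wᵀ1 + λ_H H + eps]."""
    d, n = h.shape
    numer = np.zeros((d, n))
    colsum = np.zeros(d)
    for ws, w in zip(workspaces, w_list):
        numer += w.T @ ws.ratio(w, h)
        colsum += w.sum(axis=0)
    denom = colsum[:, None] + lam_h * h + eps
    return h * numer / denom


def update_h_l2norm(
    workspaces: list[ModalityWorkspace],
    w_list: list[np.ndarray],
    h: np.ndarray,
    eps: float,
    renormalize: bool = True,
) -> np.ndarray:
    """Tangent-corrected multiplicative H-update for the unit-column-norm mode.

    With S(M) the matrix of column sums of M broadcast down each column
    (the 1_{D×D} M premultiplication):

    H ← H ⊙ [Σ_v (Wᵀ(X⊘(WH)) + H ⊙ S(Wᵀ1))]
          ⊘ [Σ_v (Wᵀ1 + H ⊙ S(Wᵀ(X⊘(WH)))) + eps]

    The correction terms keep the step tangent to the unit sphere; an explicit
    column renormalization afterwards removes residual floating-point drift.
    """
    norms = np.linalg.norm(h, axis=0)
    if np.any(norms == 0):
        raise ValueError("H has a zero column; unit-norm constraint undefined")
    d, n = h.shape
    numer = np.zeros((d, n))
    denom = np.zeros((d, n))
    w_total = 0.0
    colsum = np.zeros(d)
    for ws, w in zip(workspaces, w_list):
        p = w.T @ ws.ratio(w, h)  # Wᵀ(X⊘(WH)), D×N
        numer += p
        denom += h * p.sum(axis=0)[None, :]
        w_total += float(w.sum())  # S(Wᵀ1) is constant = ΣW
        colsum += w.sum(axis=0)
    numer += h * w_total
    denom += colsum[:, None]
    h_new = h * numer / (denom + eps)
    if renormalize:
        h_new = h_new / np.linalg.norm(h_new, axis=0)
    return h_new


def update_w_frobenius(
    ws: ModalityWorkspace,
    w: np.ndarray,
    h: np.ndarray,
    lam_w: float,
    graph,
    eps: float,
) -> np.ndarray:
    """Graph-regularized Frobenius MU for W (Lee–Seung form plus graph terms)."""
    numer = ws.x @ h.T
    denom = w @ (h @ h.T)
    if lam_w != 0.0:
        numer = numer + 0.5 * lam_w * _sym_dot(graph.lap_neg, w)
        denom = denom + 0.5 * lam_w * _sym_dot(graph.lap_pos, w)
    return w * numer / (denom + eps)


def update_h_frobenius(
    workspaces: list[ModalityWorkspace],
    w_list: list[np.ndarray],
    h: np.ndarray,
    lam_h: float,
    eps: float,
    constraint: str = "sparsity_H",
    renormalize: bool = True,
) -> np.ndarray:
    """Frobenius MU for H in either constraint mode."""
    d, n = h.shape
    if constraint == "sparsity_H":
        numer = np.zeros((d, n))
        denom = np.zeros((d, n))
        for ws, w in zip(workspaces, w_list):
            numer += w.T @ ws.x
            denom += (w.T @ w) @ h
        return h * numer / (denom + lam_h * h + eps)
    elif constraint == "l2norm_H":
        numer = np.zeros((d, n))
        denom = np.zeros((d, n))
        for ws, w in zip(workspaces, w_list):
            a = np.asarray(w.T @ ws.x)  # Wᵀ X
            b = (w.T @ w) @ h  # Wᵀ W H
            numer += a + h * b.sum(axis=0)[None, :]
            denom += b + h * a.sum(axis=0)[None, :]
        h_new = h * numer / (denom + eps)
        if renormalize:
            norms = np.linalg.norm(h_new, axis=0)
            if np.any(norms == 0):
                raise ValueError("H developed a zero column")
            h_new = h_new / norms
        return h_new
    raise ValueError(f"unknown constraint {constraint!r}")
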