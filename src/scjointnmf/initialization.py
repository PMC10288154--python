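"""Factor initialization: NNDSVD with densification and mean-sum rescaling.

Multiplicative updates cannot move an entry away from zero, so the sparse
NNDSVD output is densified (zeros replaced by the data mean) and rescaled so
that W's columns share the mean column sum and H's rows the mean row sum —
the truncated-SVD energy ordering of the factors is not a property of NMF and
would otherwise bias the solver toward the leading components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp

__all__ = ["InitConfig", "nndsvd", "densify_and_rescale", "initialize_factors"]

#: entries below this are treated as exact zeros (SVD round-off)
ZERO_TOL = 1e-12


@dataclass
class InitConfig:
    method: Literal["nndsvd", "random"] = "nndsvd"
    d: int = 10
    seed: int = 0


def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def nndsvd(x, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative Double Singular Value Decomposition (Boutsidis–Gallopoulos).

    The leading singular triplet is kept as-is (both vectors of a non-negative
    matrix's leading triplet can be taken non-negative); for every subsequent
    triplet the positive/negative part pair with the larger product of norms
    is kept, rescaled to preserve the singular value.  Deterministic: the SVD
    sign ambiguity is resolved by making each left singular vector's
    largest-magnitude entry positive.

    Returns ``(W, H)`` with shapes (M, d) and (d, N), all entries ≥ 0.
    """
    xd = _dense(x)
    m, n = xd.shape
    if d < 1 or d > min(m, n):
        raise ValueError(f"d={d} invalid for a {m}×{n} matrix")
    if xd.min() < 0:
        raise ValueError("nndsvd requires a non-negative matrix")

    u, s, vt = np.linalg.svd(xd, full_matrices=False)
    u, s, vt = u[:, :d], s[:d], vt[:d]
    # sign convention: largest-|entry| of each left vector is positive
    for j in range(d):
        i_max = int(np.argmax(np.abs(u[:, j])))
        if u[i_max, j] < 0:
            u[:, j] = -u[:, j]
            vt[j] = -vt[j]

    w = np.zeros((m, d))
    h = np.zeros((d, n))
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, d):
        uj, vj = u[:, j], vt[j]
        up, un = np.maximum(uj, 0), np.maximum(-uj, 0)
        vp, vn = np.maximum(vj, 0), np.maximum(-vj, 0)
        upn, unn = np.linalg.norm(up), np.linalg.norm(un)
        vpn, vnn = np.linalg.norm(vp), np.linalg.norm(vn)
        if upn * vpn >= unn * vnn:  # tie → positive parts
            sigma = s[j] * upn * vpn
            w[:, j] = np.sqrt(sigma) * up / upn if upn > 0 else 0.0
            h[j] = np.sqrt(sigma) * vp / vpn if vpn > 0 else 0.0
        else:
            sigma = s[j] * unn * vnn
            w[:, j] = np.sqrt(sigma) * un / unn
            h[j] = np.sqrt(sigma) * vn / vnn
    return w, h


def _matrix_mean(x) -> float:
    if sp.issparse(x):
        return float(x.sum()) / (x.shape[0] * x.shape[1])
    return float(np.mean(x))


def densify_and_rescale(
    w: np.ndarray, h: np.ndarray, x
) -> tuple[np.ndarray, np.ndarray]:
    """Replace zeros by the data mean, then equalize W column / H row sums.

    Zeros (entries below ``ZERO_TOL``) become the arithmetic mean over *all*
    entries of the source matrix ``x``; afterwards every column of W is scaled
    to the mean column sum of W and every row of H to the mean row sum of H.
    Densification precedes rescaling, so substituted values participate in the
    sums.
    """
    w = np.array(w, dtype=np.float64, copy=True)
    h = np.array(h, dtype=np.float64, copy=True)
    if not (w > ZERO_TOL).any() or not (h > ZERO_TOL).any():
        raise ValueError("cannot densify an all-zero factor matrix")
    mean = _matrix_mean(x)
    w[w < ZERO_TOL] = mean
    h[h < ZERO_TOL] = mean
    col = w.sum(axis=0)
    w *= col.mean() / col
    row = h.sum(axis=1)
    h *= (row.mean() / row)[:, None]
    return w, h


def initialize_factors(data, cfg: InitConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Initial ``(W list, H)`` for a normalized multimodal dataset.

    With ``method="nndsvd"`` each Wᵛ comes from NNDSVD of its own Xᵛ while the
    shared H comes from NNDSVD of the feature-axis concatenation of all
    modalities (so H sees every modality).  ``method="random"`` draws uniform
    (0, 1] entries from a seeded generator.  Either way the factors are
    densified and rescaled, leaving them strictly positive.
    """
    mats = [cm.values for cm in data.modalities]
    n = data.n_cells
    d = cfg.d
    bound = min(min(m.shape[0] for m in mats), n)
    if d < 1 or d >= bound:
        raise ValueError(f"d={d} must satisfy 1 <= d < min(M^v, N) = {bound}")
    for cm in data.modalities:
        if cm.flavor != "normalized":
            raise ValueError("initialize_factors expects normalized modalities")

    if cfg.method == "nndsvd":
        w_list = []
        for xv in mats:
            w, _ = nndsvd(xv, d)
            w_list.append(w)
        x_all = sp.vstack([m.tocsr() for m in mats])
        _, h = nndsvd(x_all, d)
    elif cfg.method == "random":
        rng = np.random.default_rng(cfg.seed)
        w_list = [1.0 - rng.random((m.shape[0], d)) for m in mats]
        h = 1.0 - rng.random((d, n))
        x_all = sp.vstack([m.tocsr() for m in mats])
    else:
        raise ValueError(f"unknown init method {cfg.method!r}")

    w_out = [densify_and_rescale(w, h, xv)[0] for w, xv in zip(w_list, mats)]
    _, h_out = densify_and_rescale(w_list[0], h, x_all)
    return w_out, h_out
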