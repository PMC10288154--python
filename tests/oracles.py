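"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — scalar loops, dense arrays, direct
formulas — and shares no code with the package, so agreement is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

from math import comb, lgamma, log

import numpy as np
import scipy.linalg


# ---------------------------------------------------------------------------
# multiplicative-update single steps (scalar triple loops)

def mu_step_w_kl(x, w, h, lam, lap_pos, lap_neg, eps):
    """One KL W-step with graph regularization, elementwise loops."""
    x, w, h = map(np.asarray, (x, w, h))
    m, n = x.shape
    d = w.shape[1]
    lp = np.asarray(lap_pos.todense() if hasattr(lap_pos, "todense") else lap_pos)
    ln = np.asarray(lap_neg.todense() if hasattr(lap_neg, "todense") else lap_neg)
    wh = w @ h
    out = np.empty_like(w)
    for i in range(m):
        for dd in range(d):
            num = 0.0
            for j in range(n):
                if x[i, j] != 0:
                    num += x[i, j] / wh[i, j] * h[dd, j]
            den = sum(h[dd, j] for j in range(n))
            for mm in range(m):
                num += 0.5 * lam * (ln[i, mm] + ln[mm, i]) * w[mm, dd]
                den += 0.5 * lam * (lp[i, mm] + lp[mm, i]) * w[mm, dd]
            out[i, dd] = w[i, dd] * num / (den + eps)
    return out


def mu_step_h_sparsity(x_list, w_list, h, lam_h, eps):
    """One ridge-penalized KL H-step over V modalities, elementwise loops."""
    h = np.asarray(h)
    d, n = h.shape
    out = np.empty_like(h)
    wh_list = [np.asarray(w) @ h for w in w_list]
    for dd in range(d):
        for j in range(n):
            num = 0.0
            den = 0.0
            for x, w, wh in zip(x_list, w_list, wh_list):
                x = np.asarray(x)
                w = np.asarray(w)
                for i in range(x.shape[0]):
                    if x[i, j] != 0:
                        num += w[i, dd] * x[i, j] / wh[i, j]
                    den += w[i, dd]
            out[dd, j] = h[dd, j] * num / (den + lam_h * h[dd, j] + eps)
    return out


def mu_step_h_l2norm(x_list, w_list, h, eps):
    """One unit-norm-corrected KL H-step (pre-renormalization), literal
    1_{D×D}-premultiplied correction terms."""
    h = np.asarray(h)
    d, n = h.shape
    ones_dd = np.ones((d, d))
    num = np.zeros((d, n))
    den = np.zeros((d, n))
    for x, w in zip(x_list, w_list):
        x, w = np.asarray(x), np.asarray(w)
        m = x.shape[0]
        wh = w @ h
        ratio = np.where(x != 0, x / wh, 0.0)
        a = w.T @ ratio
        b = w.T @ np.ones((m, n))
        num += a + h * (ones_dd @ b)
        den += b + h * (ones_dd @ a)
    return h * num / (den + eps)


# ---------------------------------------------------------------------------
# textbook unpenalized NMF (dense Lee–Seung updates)

def kl_nmf_textbook(x, w, h, n_iter):
    """Classical KL-NMF multiplicative updates, dense, W before H."""
    x = np.asarray(x, dtype=float)
    w = np.array(w, dtype=float)
    h = np.array(h, dtype=float)
    for _ in range(n_iter):
        wh = w @ h
        w = w * ((x / wh) @ h.T) / h.sum(axis=1)[None, :]
        wh = w @ h
        h = h * (w.T @ (x / wh)) / w.sum(axis=0)[:, None]
    return w, h


def frobenius_nmf_textbook(x, w, h, n_iter):
    x = np.asarray(x, dtype=float)
    w = np.array(w, dtype=float)
    h = np.array(h, dtype=float)
    for _ in range(n_iter):
        w = w * (x @ h.T) / (w @ (h @ h.T))
        h = h * (w.T @ x) / ((w.T @ w) @ h)
    return w, h


# ---------------------------------------------------------------------------
# NNDSVD reference (independent construction, plain loops)

def nndsvd_reference(x, d):
    x = np.asarray(x, dtype=float)
    u, s, vt = scipy.linalg.svd(x, full_matrices=False)
    w = np.zeros((x.shape[0], d))
    h = np.zeros((d, x.shape[1]))
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0, :] = np.sqrt(s[0]) * np.abs(vt[0, :])
    for j in range(1, d):
        uj = u[:, j]
        vj = vt[j, :]
        up = np.array([max(t, 0.0) for t in uj])
        un = np.array([max(-t, 0.0) for t in uj])
        vp = np.array([max(t, 0.0) for t in vj])
        vn = np.array([max(-t, 0.0) for t in vj])
        n_up, n_un = np.sqrt((up**2).sum()), np.sqrt((un**2).sum())
        n_vp, n_vn = np.sqrt((vp**2).sum()), np.sqrt((vn**2).sum())
        if n_up * n_vp >= n_un * n_vn:
            uu, vv, mu = up / n_up, vp / n_vp, n_up * n_vp
        else:
            uu, vv, mu = un / n_un, vn / n_vn, n_un * n_vn
        w[:, j] = np.sqrt(s[j] * mu) * uu
        h[j, :] = np.sqrt(s[j] * mu) * vv
    return w, h


# ---------------------------------------------------------------------------
# KNN graph by exhaustive search

def knn_adjacency_bruteforce(coords, k):
    """Union-symmetrized KNN adjacency; ties broken by smaller index."""
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    adj = np.zeros((m, m))
    for i in range(m):
        cand = []
        for j in range(m):
            if j != i:
                cand.append((float(((coords[i] - coords[j]) ** 2).sum()), j))
        cand.sort()
        for _, j in cand[:k]:
            adj[i, j] = 1.0
            adj[j, i] = 1.0
    return adj


# ---------------------------------------------------------------------------
# partition-agreement scores from first principles

def ari_bruteforce(a, b):
    """Hubert–Arabie adjusted Rand index from the contingency table."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    nij = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub] for x in ua])
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in ai)
    sum_b = sum(comb(int(v), 2) for v in bj)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if np.array_equal(nij, np.diag(np.diag(nij))) else 0.0
    return (sum_ij - expected) / (max_index - expected)


def _entropy(counts, n):
    h = 0.0
    for c in counts:
        if c > 0:
            h -= (c / n) * log(c / n)
    return h


def _expected_mutual_information(ai, bj, n):
    """EMI under the hypergeometric permutation model (direct summation)."""
    emi = 0.0
    for a in ai:
        for b in bj:
            lo = max(1, a + b - n)
            hi = min(a, b)
            for nij in range(lo, hi + 1):
                term1 = nij / n * log(n * nij / (a * b))
                lg = (
                    lgamma(a + 1) + lgamma(b + 1) + lgamma(n - a + 1) + lgamma(n - b + 1)
                    - lgamma(n + 1) - lgamma(nij + 1) - lgamma(a - nij + 1)
                    - lgamma(b - nij + 1) - lgamma(n - a - b + nij + 1)
                )
                emi += term1 * np.exp(lg)
    return emi


def ami_bruteforce(a, b):
    """Adjusted mutual information, max-entropy normalization."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    nij = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub] for x in ua])
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    mi = 0.0
    for i in range(len(ua)):
        for j in range(len(ub)):
            if nij[i, j] > 0:
                mi += nij[i, j] / n * log(n * nij[i, j] / (ai[i] * bj[j]))
    emi = _expected_mutual_information(ai, bj, n)
    ha, hb = _entropy(ai, n), _entropy(bj, n)
    denom = max(ha, hb) - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom


# ---------------------------------------------------------------------------
# dense objective evaluation

def kl_objective_dense(x_list, w_list, h, laplacians, lambda_w, lambda_h):
    """Elementwise KL objective with 0·log 0 = 0, fully dense."""
    total = 0.0
    h = np.asarray(h)
    for x, w, lap, lam in zip(x_list, w_list, laplacians, lambda_w):
        x = np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=float)
        w = np.asarray(w)
        wh = w @ h
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                if x[i, j] > 0:
                    total += x[i, j] * log(x[i, j] / wh[i, j]) - x[i, j] + wh[i, j]
                else:
                    total += wh[i, j]
        lapd = np.asarray(lap.todense() if hasattr(lap, "todense") else lap)
        total += 0.5 * lam * float(np.trace(w.T @ lapd @ w))
    total += 0.5 * lambda_h * float((h**2).sum())
    return total
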