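"""Cluster-structured multimodal Poisson count simulator with ground truth.

The generator produces paired modalities (by default an RNA-like 900-feature
and an ATAC-like 5,800-feature matrix over 3 clusters × 100 cells) from a
transparent Poisson factor model matched to the factorization's own
assumptions:

1. each cluster owns an exclusive block of latent factors whose prototype
   loadings are boosted by ``separation``; a cell's true loading vector is its
   cluster prototype plus positive within-cluster jitter;
2. per-modality feature loadings are sparse Gamma draws with a guaranteed
   high loading on each feature's "home" factor;
3. rates Wᵛ·H are rescaled to a realistic per-kind library size, multiplied
   by log-normal per-cell size factors, and Poisson-sampled;
4. two noise-injection protocols mirror common RNA/ATAC noise models: RNA
   noise multiplies each feature's rate by a U(1, c) draw before sampling;
   ATAC noise adds per-entry Gaussian N(−m, m) to the sampled counts, which
   are then rounded and clipped at zero.

Noise tiers (c, m): low (1.25, 0.25), mid (1.5, 0.5), high (2, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, MultiModalDataset, write_counts, write_labels

__all__ = ["SimConfig", "SimTruth", "simulate_multimodal", "inject_noise", "write_dataset"]

#: upper bound c of the per-feature U(1, c) variability multiplier (RNA protocol)
RNA_NOISE_LEVELS = {"none": None, "low": 1.25, "mid": 1.5, "high": 2.0}
#: magnitude m of the additive per-entry N(−m, m) noise (ATAC protocol)
ATAC_NOISE_LEVELS = {"none": None, "low": 0.25, "mid": 0.5, "high": 1.0}

#: baseline per-feature biological variability (variance of the mean-1 Gamma
#: multiplicative rate noise) of RNA-like modalities; noise levels scale it
RNA_BASE_VARIABILITY = 0.3

#: mean library size targeted per modality kind; joint RNA+chromatin protocols
#: recover far fewer counts per cell per assay than either assay alone
TARGET_LIBRARY = {"rna": 400.0, "atac": 600.0, "other": 400.0}

# prototype / jitter shape constants of the latent factor model
_PROTO_BASE_SHAPE, _PROTO_BASE_SCALE = 4.0, 0.075  # baseline loading Gamma (mean 0.3)
_BLOCK_SHAPE, _BLOCK_SCALE = 25.0, 0.06  # block boost Gamma (mean 1.5, low var)
_JITTER_SCALE = 0.15  # within-cluster Gamma(1, ·) jitter per factor
_W_DENSITY = 0.10  # off-home-factor sparsity of feature loadings
_W_BG_SCALE = 0.2  # off-home Gamma(1, ·) scale
_W_HOME_SHAPE, _W_HOME_SCALE = 4.0, 1.0  # home-factor Gamma loading
#: probability that a feature's home factor is cluster-exclusive; accessibility
#: is more cell-type specific than expression, so ATAC features concentrate on
#: the exclusive block while RNA features spread uniformly over all factors
_EXCLUSIVE_HOME_FRAC = {"rna": None, "atac": 0.6, "other": None}


@dataclass
class SimConfig:
    """Study-design parameters; defaults mirror the 3 × 100-cell paired
    RNA (~900 features) / ATAC (~5,800 features) benchmark scale."""

    n_clusters: int = 3
    cells_per_cluster: int = 100
    features_per_modality: Sequence[int] = (900, 5800)
    modality_kinds: Sequence[str] = ("rna", "atac")
    d_true: int = 10
    noise_level: str = "none"
    separation: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_level not in RNA_NOISE_LEVELS:
            raise ValueError(
                f"noise_level must be one of {sorted(RNA_NOISE_LEVELS)}"
            )
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if len(self.features_per_modality) != len(self.modality_kinds):
            raise ValueError("features_per_modality and modality_kinds lengths differ")
        n = self.n_clusters * self.cells_per_cluster
        if self.d_true >= min(min(self.features_per_modality), n):
            raise ValueError("d_true must be below min(M^v, N)")


@dataclass
class SimTruth:
    """Ground truth: rate^v = W_true^v @ H_true entrywise (before noise)."""

    labels: np.ndarray
    H_true: np.ndarray
    W_true: list
    rate: list
    size_factors: np.ndarray
    noise_level: str
    noise_params: dict
    seed: int


def inject_noise(counts, kind: str, level: str, seed=0):
    """Apply one modality's noise protocol.

    ``kind="atac"`` operates on sampled integer counts: per-entry Gaussian
    N(−m, m) is added, entries are rounded to the nearest integer and clipped
    at zero.  ``kind="rna"`` operates on a *rate* matrix (noise enters before
    Poisson sampling, as inside :func:`simulate_multimodal`): each feature's
    variability parameter — the variance of a mean-1 multiplicative Gamma
    noise on its rate — is the baseline ``RNA_BASE_VARIABILITY`` scaled by an
    independent U(1, c) draw, so higher levels overdisperse the counts
    without inflating library sizes.  ``level="none"`` returns the input
    unchanged.
    """
    if level not in RNA_NOISE_LEVELS:
        raise ValueError(f"unknown noise level {level!r}")
    if level == "none":
        return counts
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "atac":
        m = ATAC_NOISE_LEVELS[level]
        dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=np.float64)
        noisy = dense + rng.normal(-m, m, size=dense.shape)
        noisy = np.clip(np.rint(noisy), 0, None)
        return sp.csr_matrix(noisy) if sp.issparse(counts) else noisy
    if kind in ("rna", "other"):
        c = RNA_NOISE_LEVELS[level]
        rate = np.asarray(counts, dtype=np.float64)
        u = rng.uniform(1.0, c, size=rate.shape[0])
        return rate * _gamma_dispersion(rng, RNA_BASE_VARIABILITY * u, rate.shape)
    raise ValueError(f"unknown modality kind {kind!r}")


def _gamma_dispersion(rng, variability, shape) -> np.ndarray:
    """Mean-1 Gamma multiplicative noise with per-feature variance."""
    v = np.broadcast_to(np.asarray(variability, dtype=np.float64)[:, None], shape)
    return rng.gamma(shape=1.0 / v, scale=v)


def simulate_multimodal(cfg: SimConfig) -> tuple[MultiModalDataset, SimTruth]:
    """Generate one multimodal dataset plus its generating truth.

    Deterministic given ``cfg.seed``; returns raw integer
    :class:`CountMatrix` modalities and a :class:`SimTruth`.
    """
    rng = np.random.default_rng(cfg.seed)
    k, d = cfg.n_clusters, cfg.d_true
    n = k * cfg.cells_per_cluster
    labels = np.repeat(np.arange(k), cfg.cells_per_cluster)

    # the first k factors form the cluster-exclusive block (factor c belongs
    # to cluster c); remaining factors are shared background structure, so
    # only the features homed on exclusive factors discriminate clusters
    factor_owner = np.where(np.arange(d) < k, np.arange(d) % k, -1)
    shared = rng.gamma(shape=_PROTO_BASE_SHAPE, scale=_PROTO_BASE_SCALE, size=d)
    prototypes = np.empty((k, d))
    for c in range(k):
        proto = shared.copy()
        own = factor_owner == c
        proto[own] += cfg.separation * rng.gamma(
            shape=_BLOCK_SHAPE, scale=_BLOCK_SCALE, size=own.sum()
        )
        prototypes[c] = proto
    jitter = rng.gamma(shape=1.0, scale=_JITTER_SCALE, size=(n, d))
    h_true = (prototypes[labels] + jitter).T  # D × N, strictly positive

    size = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    size /= size.mean()

    modalities, w_list, rate_list = [], [], []
    noise_params = {
        "rna_multiplier_upper": RNA_NOISE_LEVELS[cfg.noise_level],
        "atac_gaussian_m": ATAC_NOISE_LEVELS[cfg.noise_level],
    }
    for v, (m, kind) in enumerate(zip(cfg.features_per_modality, cfg.modality_kinds)):
        frac = _EXCLUSIVE_HOME_FRAC.get(kind)
        if frac is None:
            home = np.arange(m) % d
        else:
            excl = rng.random(m) < frac
            home = np.where(
                excl,
                rng.integers(0, k, size=m),
                rng.integers(k, d, size=m) if d > k else rng.integers(0, k, size=m),
            )
        w = np.where(
            rng.random((m, d)) < _W_DENSITY,
            rng.gamma(shape=1.0, scale=_W_BG_SCALE, size=(m, d)),
            0.0,
        )
        w[np.arange(m), home] = rng.gamma(
            shape=_W_HOME_SHAPE, scale=_W_HOME_SCALE, size=m
        )
        rate = w @ h_true
        # fold the library-size calibration into the true loadings so that
        # rate == W_true @ H_true holds exactly
        scale = TARGET_LIBRARY.get(kind, TARGET_LIBRARY["other"]) / rate.sum(axis=0).mean()
        w *= scale
        rate *= scale

        sampling_rate = rate
        if kind in ("rna", "other"):
            if cfg.noise_level == "none":
                # biological overdispersion at its baseline variability
                sampling_rate = rate * _gamma_dispersion(
                    rng, np.full(m, RNA_BASE_VARIABILITY), rate.shape
                )
            else:
                sampling_rate = inject_noise(rate, "rna", cfg.noise_level, rng)
        counts = rng.poisson(sampling_rate * size[None, :]).astype(np.float64)
        if kind == "atac" and cfg.noise_level != "none":
            counts = inject_noise(counts, "atac", cfg.noise_level, rng)

        modalities.append(
            CountMatrix(
                sp.csr_matrix(counts),
                feature_ids=[f"{kind}{v}_feat{i}" for i in range(m)],
                cell_ids=[f"cell{j}" for j in range(n)],
                modality_name=kind,
                flavor="raw",
            )
        )
        w_list.append(w)
        rate_list.append(rate)

    truth = SimTruth(
        labels=labels,
        H_true=h_true,
        W_true=w_list,
        rate=rate_list,
        size_factors=size,
        noise_level=cfg.noise_level,
        noise_params=noise_params,
        seed=cfg.seed,
    )
    return MultiModalDataset(modalities, labels=labels), truth


def write_dataset(data: MultiModalDataset, cfg: SimConfig, outdir) -> None:
    """Write MTX directories per modality, labels.csv, and the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cm in data.modalities:
        write_counts(cm, outdir / cm.modality_name, format="mtx_dir")
    if data.labels is not None:
        write_labels(data.cell_ids, data.labels, outdir / "labels.csv")
    record = asdict(cfg)
    record["features_per_modality"] = list(cfg.features_per_modality)
    record["modality_kinds"] = list(cfg.modality_kinds)
    (outdir / "sim_config.json").write_text(json.dumps(record, indent=2))
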