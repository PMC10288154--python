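# scjointnmf

Joint graph-regularized KL-divergence NMF for clustering cells from
multimodal single-cell count data (e.g. paired scRNA-seq + scATAC-seq).

## The problem

Multimodal single-cell assays measure several omics layers — typically gene
expression and chromatin accessibility — in the *same* cells. Each modality
alone gives a noisy, partial view of cell identity; clustering cells well
requires integrating them. This package factorizes all modalities jointly
around one shared low-dimensional representation of the cells, and is aimed
at analysts who have CellRanger-style count matrices (features × cells) per
modality and want cell clusters plus the factor loadings that explain them.

## The model

Given V modalities of median-library-size-normalized count matrices
X¹ … Xᵛ (Xᵛ is Mᵛ × N, columns are the same N cells in the same order), the
method solves

    min_{Wᵛ ≥ 0, H ≥ 0}  Σᵥ D(Xᵛ ‖ Wᵛ H)  +  Σᵥ ½ λ_Wᵛ tr(WᵛᵀLᵛWᵛ)  +  penalty(H)

* **D** is the Poisson KL divergence Σᵢⱼ [x log(x/μ) − x + μ] with μ = (WᵛH)ᵢⱼ
  (a squared Frobenius alternative is provided for continuous data);
* **H** (D × N) is shared across modalities — each cell's D-dimensional
  loading vector, which is what gets clustered;
* **Wᵛ** (Mᵛ × D) are per-modality feature loadings;
* **Lᵛ = Dᵛ − Aᵛ** is the Laplacian of a feature–feature similarity graph
  (by default a union-symmetrized Euclidean KNN graph built from the raw
  counts); tr(WᵛᵀLᵛWᵛ) pulls similar features toward similar loadings.
  With Lᵛ = I the penalty reduces exactly to the ridge ½ λ ‖Wᵛ‖²_F;
* **penalty(H)** is either the ridge ½ λ_H ‖H‖²_F (`sparsity_H`) or the
  constraint that every column of H has unit L2 norm (`l2norm_H`), enforced
  by a tangent-corrected multiplicative update.

Optimization uses multiplicative updates (each parameter times the ratio of
the negative to the positive part of its gradient) from a strictly positive
NNDSVD-based initialization, so non-negativity is preserved at every step.
Cells are then clustered with restarted k-means on the columns of H and
scored against reference labels with ARI/AMI when labels exist. Recommended
regularization weights for paired RNA/ATAC data are λ_W = (10, 50), λ_H = 500
in `sparsity_H` mode and λ_W = (3, 15) in `l2norm_H` mode.

## Worked example

```python
import numpy as np
from scjointnmf import SimConfig, simulate_multimodal, run_pipeline

# a labeled synthetic benchmark: 3 cell types x 100 cells,
# 900 RNA features + 5,800 ATAC features, mid-tier noise
cfg = SimConfig(noise_level="mid", seed=7)
data, truth = simulate_multimodal(cfg)

result = run_pipeline(data, n_components=10, n_clusters=3,
                      max_iter=200, loss_every=25, seed=0)

print("modalities:", [(cm.modality_name, cm.values.shape) for cm in data.modalities])
print("converged:", result.model.converged, "after", result.model.iterations_run, "iterations")
print("final objective: %.1f" % result.model.loss_trace[-1][1])
print("cluster sizes:", np.bincount(result.clusters.labels))
print("ARI vs ground truth: %.3f" % result.ari)
print("AMI vs ground truth: %.3f" % result.ami)
```

Output:

```
modalities: [('rna', (900, 300)), ('atac', (5800, 300))]
converged: False after 200 iterations
final objective: 484408.2
cluster sizes: [102  97 101]
ARI vs ground truth: 0.951
AMI vs ground truth: 0.923
```

`run_pipeline` filtered features present in fewer than 10 cells, built one
KNN feature graph per modality from the raw counts, normalized, fit the
joint factorization with the default λ bundle, and clustered H. An ARI of
0.95 means the recovered partition almost coincides with the generating cell
types despite the injected noise; the objective is still the full penalized
loss (its absolute value scales with the count mass and is only meaningful
relative to other fits of the same data).

The same workflow is available from the shell:

```bash
scjointnmf simulate --out sim --noise-level mid --seed 7
scjointnmf pipeline --modality sim/rna --modality sim/atac \
    --kind rna --kind atac --d 10 --n-clusters 3 \
    --labels sim/labels.csv --max-iter 200 --loss-every 25 --out run
```

Other subcommands: `preprocess`, `graph`, `select-d` (elbow scan over D),
`fit`, `cluster` (with silhouette/WSS/gap diagnostics), `evaluate`.

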