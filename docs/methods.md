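# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the limits of what the test suite demonstrates.

## Model and objective

For V modalities of normalized count matrices Xᵛ (Mᵛ × N, columns = cells,
identical cell order everywhere), the factorization minimizes

    Σᵥ D(Xᵛ ‖ WᵛH) + Σᵥ ½ λ_Wᵛ tr(WᵛᵀLᵛWᵛ) + penalty(H),

over Wᵛ ≥ 0 (Mᵛ × D) and a shared H ≥ 0 (D × N). The data-fit term D is the
Poisson KL divergence Σ [x log(x/μ) − x + μ], the natural discrepancy when
each entry is modeled as Poisson with rate (WᵛH)ᵢⱼ; median library size
normalization rescales cells without destroying the count-like magnitudes
this reading needs. A squared-Frobenius data fit is available for continuous
data and shares the penalty structure.

Assumptions worth stating: all modalities are measured on the same cells and
carry the *same* cluster structure through the shared H; rates WᵛH are
strictly positive wherever a count is observed; and features within a
modality have comparable scales after normalization (the graph penalty
couples them directly).

The H penalty comes in two modes:

* `sparsity_H` — ridge ½ λ_H ‖H‖²_F shrinking all cell loadings;
* `l2norm_H` — each *column* of H (one cell's loading vector) constrained to
  unit L2 norm. The phrase "rows of H" in some formulations refers to the
  N × D transpose; here the constraint is per cell either way, and it is
  applied per column of the D × N H.

## Optimization

Multiplicative updates: each parameter is multiplied by the elementwise
ratio of the negative to the positive part of its gradient. The W-step is

    W ← W ⊙ [(X⊘(WH))Hᵀ + ½λ([L]⁻W + [L]⁻ᵀW)] ⊘ [1Hᵀ + ½λ([L]⁺W + [L]⁺ᵀW) + ε]

where [L]⁺/[L]⁻ are the elementwise positive/negative parts of L (for an
unweighted graph: the degree diagonal and the adjacency). The ridge-mode
H-step divides Σᵥ Wᵛᵀ(X⊘(WH)) by Σᵥ Wᵛᵀ1 + λ_H H + ε; λ_H enters once, not
once per modality, matching the gradient of the objective. The unit-norm
H-step adds the tangent-correction terms H ⊙ S(Wᵛᵀ1) (numerator) and
H ⊙ S(Wᵛᵀ(X⊘(WH))) (denominator), S(·) being the column-sum operator; these
keep the step approximately norm-preserving, and an explicit renormalization
of every column afterwards removes residual floating-point drift. No
compensating rescale of Wᵛ is applied — the next W-step reabsorbs scale.

Per iteration, all Wᵛ are updated in modality order against the current H,
then H against the fresh Wᵛ. The loop stops when the relative change of the
full objective (data fit plus all penalties) between consecutive evaluations
falls below `tol`, or at `max_iter`. Defaults: `max_iter` 10,000, `tol` 1e-6,
objective evaluated every iteration (`loss_every` raises this for speed; the
convergence test then compares evaluations `loss_every` iterations apart).

Numerical choices:

* ε = 1e-16 is added to MU denominators only — never to numerators, never
  inside logarithms — so fixed points are not biased at any representable
  scale.
* X⊘(WH) is materialized only on X's nonzero support (the ratio is zero
  elsewhere and only products against it are needed). (WH) values on the
  support come from a dense BLAS product when M·N is small enough, else from
  chunked row gathers; `1Hᵀ`, `Wᵀ1` and Σᵢⱼ(WH) collapse to factor sums.
* A zero rate at an observed count (infinite divergence) raises an error
  rather than being floored; with strictly positive initialization it cannot
  occur.
* The ridge-mode KL objective is provably non-increasing under these updates
  and the suite asserts it per iteration; the unit-norm mode can fluctuate
  at the renormalization step, so there the running minimum and the overall
  initial-to-final decrease are asserted instead.

## Initialization

NNDSVD (double non-negative SVD): the leading singular triplet is kept
as-is; for each later triplet the positive/negative part pair with the
larger product of norms is kept, rescaled to preserve the singular value.
The SVD sign ambiguity is resolved by making each left singular vector's
largest-magnitude entry positive, and ties in the part selection fall to the
positive parts, so the initialization is fully deterministic. Each Wᵛ comes
from NNDSVD of its own Xᵛ; the shared H from NNDSVD of the feature-axis
concatenation of all modalities.

Because multiplicative updates cannot leave zero, exact zeros (entries below
1e-12, SVD round-off included) are replaced by the arithmetic mean over all
entries of the corresponding data matrix. Densification happens first; then
every column of W is scaled to the mean W column sum and every row of H to
the mean H row sum (substituted values participate in the sums). The
rescaling matters because truncated-SVD components decay in energy while NMF
factors need not. Random initialization (uniform (0, 1], seeded, then the
same rescaling) is provided for comparison and is measurably worse on the
benchmark — the acceptance script quantifies the gap.

## Feature graphs

Graph nodes are features; coordinates are the raw counts across cells
(normalization would rescale cells and distort feature geometry). Each
feature is linked to its k nearest Euclidean neighbors (default k = 10, the
customary KNN-graph default), the directed relation is symmetrized by union,
and edges are unweighted. Distance ties are broken by feature index via a
stable (distance, index) sort over an argpartition candidate pool, so graph
construction is deterministic and permutation-equivariant. Construction
refuses N ≥ Mᵛ — with more cells than features, Euclidean feature distances
are not trustworthy and an external graph (edge-list file; weighted edges
allowed, invariants hold with weighted degrees) should be supplied instead.
The graph is built on the same filtered feature set that enters the
factorization so rows of Wᵛ and graph nodes align; this is asserted by id
comparison when ids are present.

## Choosing D and λ

D is chosen visually: for each candidate (default grid 2–20) the model is
initialized with NNDSVD and run for a fixed small budget — 100 iterations in
`sparsity_H` mode, 1 in `l2norm_H` mode, whose corrected update is costlier
and whose early losses already separate candidates — and the final objective
is plotted against D. The bend ("elbow") is the recommended D. A
max-distance-to-chord annotation is offered but never auto-selects, since
the curve's shape, not a single number, is the evidence. The λ defaults
(10/50/500 ridge mode, 3/15 unit-norm mode for RNA/ATAC) are the bundles
that work well for paired RNA/ATAC data; `lambda_grid_search` fits a grid of
(λ_Wᵛ, λ_H) combinations and reports post-hoc ARI when labels exist.

## Clustering and evaluation

Cells (columns of H, used as-is; unit-norm mode already normalizes them) are
clustered by k-means with 25 seeded restarts. Diagnostics over k (default
2–10): mean silhouette width, within-cluster sum of squares, and the gap
statistic against B = 50 uniform-box reference draws with the usual
sd·√(1+1/B) standard error. To keep WSS non-increasing in k despite restart
randomness, each k is additionally warm-started from the previous solution's
centers plus the worst-fit point, and the better of warm start and restarts
is kept. ARI is the Hubert–Arabie chance-corrected Rand index; AMI uses the
hypergeometric expected-MI correction with max-entropy normalization. Both
are delegated to scikit-learn and cross-checked in the tests against
first-principles implementations.

## Synthetic data generator

The generator produces paired RNA-like and ATAC-like count matrices with
ground truth from a Poisson factor model matched to the method's own
assumptions — deliberately transparent so recovery has a clean oracle. It
does **not** reimplement the Gamma-multivariate-hypergeometric or
Bernoulli-Poisson-hurdle machinery of dedicated simulators.

Design (defaults): 3 clusters × 100 cells; 900 RNA and 5,800 ATAC features;
10 true factors of which the first 3 are cluster-exclusive (one per cluster)
and the rest shared background, so only features homed on exclusive factors
discriminate clusters. Cluster prototypes are a shared Gamma baseline (mean
0.3) plus `separation` × Gamma(25, 0.06) (mean 1.5·separation, deliberately
low variance so the difficulty is stable across seeds) on the exclusive
factor; each cell adds Gamma(1, 0.15) jitter. Feature loadings are
sparse-Gamma with a guaranteed strong home-factor entry; ATAC features'
homes are biased 60% toward the exclusive block (accessibility is more
cell-type specific than expression), RNA homes are uniform. Rates WᵛH are
rescaled to mean library sizes of 400 (RNA) and 600 (ATAC) — the modest
depths typical of joint protocols after QC — multiplied by log-normal
(σ = 0.25) cell size factors, and Poisson-sampled.

Noise protocols mirror how RNA and ATAC simulators inject noise:

* RNA: each feature's variability parameter — the variance of a mean-1
  Gamma multiplicative noise on its rate — is a baseline of 0.3 scaled by a
  per-feature U(1, c) draw, c = 1.25/1.5/2 for low/mid/high. Noise raises
  overdispersion without inflating library sizes; at level `none` the
  baseline variability still applies (it is biology, not injected noise).
* ATAC: after sampling, per-entry Gaussian N(−m, m) with m = 0.25/0.5/1 is
  added and entries are rounded to integers and clipped at zero (rounding
  and clipping restore count validity; this is why the realized mean shift
  is smaller than m at low tiers).

`separation = 0.65` was calibrated once and frozen together with the library
targets: zero-noise recovery is near-perfect (mean ARI ≈ 0.98 over ten
seeds) while the tiers degrade monotonically to ≈ 0.96 at `high` — the
qualitative shape the benchmark asserts. What passing these tests shows:
the full pipeline recovers planted structure of realistic dimension, depth
and sparsity, and degrades gracefully with noise. What it does not show:
robustness to batch effects, doublets, ambient contamination, feature-length
or GC biases, zero inflation beyond Poisson sparsity, or chromatin
co-accessibility structure — none of which the generator emulates.

## Benchmark protocol

The recovery benchmark (acceptance tests and `scripts/acceptance.py`) runs
the full pipeline at the generator's default scale with D = 10, the default
λ bundle, k-means at k = 3, and a solver budget of 200 iterations
(`tol` 1e-6, objective evaluated every 25 iterations). Loss traces at this
problem size plateau well before 200 iterations, so the shortened budget is
the package's chosen benchmark protocol; production fits keep the 10,000 /
1e-6 defaults. Tests use ten generator seeds; the acceptance script uses
five seeds derived from its `--seed`.

## Known limitations

* Multiplicative updates converge slowly near stationary points; no
  second-order or block-coordinate acceleration is provided.
* The unit-norm mode's objective is not guaranteed monotone through the
  renormalization safeguard (observed fluctuations are at round-off scale).
* No out-of-sample projection: H covers the fitted cells only.
* KNN feature graphs require M > N per modality; otherwise supply an
  external graph.
* The Itakura-Saito divergence and per-modality mixed objectives are
  deliberately out of scope.
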