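# Methods

## Connectivity model

The estimator treats every region's unit-normalized time-series as a linear
combination of all other regions' series:

    min_W  ½‖X − XW‖_F² + μ₁‖W‖₁ + μ₂‖W‖_*   s.t. diag(W) = 0.

The l1 term encodes the belief that direct interactions are few; the nuclear
norm (an l1 penalty on singular values) encodes modularity — the coefficient
matrix of a networked system concentrates in a low-dimensional subspace. The
zero-diagonal constraint removes self-regression. Columns of `X` must be
unit-normalized first so that the fixed penalty weights are on a consistent
scale; `unit_normalize` divides each column by its Euclidean norm without
demeaning by default (a `demean=True` switch is provided — after demeaning,
the Gram matrix becomes the correlation matrix up to scale, which changes
the penalties' meaning slightly; both behaviours are deliberate options
because bandpass-filtered physiological signals are near-zero-mean anyway).

### ADMM solver

Split variables Z₁ (l1) and Z₂ (nuclear) are coupled to W through an
augmented Lagrangian with penalty parameters β₁, β₂. Per iteration:

1. `W ← (XᵀX + (β₁+β₂)I)⁻¹ (XᵀX + β₁Z₁ + Y₁ + β₂Z₂ + Y₂)`, then the
   diagonal is zeroed. The SPD system is solved by a fresh Cholesky
   factorization each iteration (N is small, ≈30–90; correctness over
   caching).
2. `Z₁ ← soft_threshold(W − Y₁/β₁, s·μ₁/β₁)`,
   `Z₂ ← SVT(W − Y₂/β₂, s·μ₂/β₂)`.
3. Dual ascent `Yᵢ ← Yᵢ + βᵢ(Zᵢ − W)`; `βᵢ ← min(β_max, ρβᵢ)`.

Defaults: μ₁ = 0.25, μ₂ = 0.1, β_init = 0.1, ρ = 1.1, β_max = 1e10,
tol = 1e-6, max_iter = 500.

**The factor s (`prox_scale`).** The published update rule thresholds at
`2μ/β`. The standard proximal derivation of the augmented Lagrangian gives
`μ/β`; a threshold of `2μ/β` is *exactly* the standard iteration applied to
the objective with both penalty weights doubled. The package keeps the
published rule as the default (`paper_factor_2`, s = 2) and exposes
`standard_factor_1` (s = 1). To keep comparisons honest, every objective
trace and every oracle test uses the **effective** objective
`½‖X−XW‖² + s·μ₁‖W‖₁ + s·μ₂‖W‖_*` for the chosen s.

**Stopping rule.** Convergence is declared when
`max(‖Z₁−W‖_F, ‖Z₂−W‖_F, ‖W_k−W_{k−1}‖_F) / max(1, ‖W‖_F) < tol`.
The primal residuals alone are not sufficient: with μ₁ = μ₂ = 0 the split
variables copy W exactly, both primal residuals are identically zero from
the first iteration, and a primal-only rule would stop at a heavily
ridge-biased iterate. The W-step change is the usual dual-residual proxy
and certifies convergence in that corner case too.

**Accuracy vs. β growth.** Zeroing the diagonal *after* the unconstrained
quadratic solve (rather than solving the constrained subproblem) makes the
fixed point exact only in the β → ∞ limit: at finite β the discarded
diagonal perturbs the optimality condition by O(1/β). With the default
ρ = 1.1 the duals effectively freeze once β is large, leaving a relative
objective gap of order 1e-2–1e-3 on small instances. When high accuracy
matters (oracle comparisons), run with ρ = 1.005 and tol = 1e-13: the
measured gap against an independent convex solver is then below 1e-3
(typically ~1e-4) across a grid of penalty weights. The default
configuration is kept as published; it is accurate enough for network
construction, where the subsequent thresholding dominates.

### Baselines

* **CORR** — absolute Pearson correlation, diagonal zeroed (negative values
  flipped, the common practice for weighted-graph analysis).
* **PCORR** — sample covariance (denominator T−1), Moore–Penrose
  pseudo-inverse with relative cutoff 1e-10, partial correlations
  `−Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ)`, absolute value. Entries whose diagonal precision
  vanishes are set to 0.
* **MVRC** — the elastic-net variant `½‖X−XW‖² + λ₁‖W‖₁ + (λ₂/2)‖W‖_F²`,
  solved with the same ADMM scaffolding; the Z₂ subproblem becomes the
  closed-form ridge shrink `(β₂W − Y₂)/(β₂ + s·λ₂)`. The exact penalty
  scaling of the original elastic-net formulation is not restated in the
  low-rank method's description, so this reconstruction (Frobenius term
  with the ½ factor) is pinned down explicitly and tested against the same
  convex oracle.

All estimators output `A = (|W|+|Wᵀ|)/2` (or are symmetric already):
symmetric, non-negative, zero diagonal.

## Overlapping community detection

A non-negative adjacency A is modelled entrywise as Poisson with rate
`(PQ)ᵢⱼ`; maximizing the (penalized) likelihood over P ∈ R^{N×K} ≥ 0,
Q ∈ R^{K×N} ≥ 0 gives multiplicative updates

    Q ← (Q ⊘ (Pᵀ1 + BQ)) ⊙ [Pᵀ(A ⊘ PQ)]
    P ← (P ⊘ (1Qᵀ + PB)) ⊙ [(A ⊘ PQ)Qᵀ]

with B = diag(β₁..β_K) a shrinkage matrix from half-normal priors on the
factor columns. Defaults follow the source description: uniform-[0,1]
random initialization, 100 iterations, 10 restarts keeping the lowest
final cost. `beta_mode="fixed"` (default β=0 → plain KL-NMF, whose cost is
provably non-increasing) or `"gamma_update"`, which re-estimates
`β_k = (2N + a − 1)/(½(‖P_k‖² + ‖Q_k‖²) + b)` from a Gamma(a=5, b=2)
hyper-prior each sweep — the hyper-prior constants are this package's
choice, as the source defers them to its reference implementation.
Divisions are guarded by `max(·, 1e-12)`. Both factors are updated
independently; only P is used for membership. The zero diagonal of A is
factorized as-is (no masking).

**Canonicalization.** The factorization has two gauge freedoms: column
order, and a per-component scale (P_k → cP_k, Q_k → Q_k/c leaves PQ
unchanged; with B=0 nothing in the cost fixes c). `nmf_restarts` therefore
rebalances each component to ‖P_k‖ = ‖Q_k‖ and orders columns by
descending column sum (ties broken by original index, stable). After
canonicalization, independent restarts on block-structured input agree to
~2% relative Frobenius distance, reproducing the observation that restarts
differ only by column exchange.

**Thresholding.** Region i joins community k iff
`P_ik > mean(P[:,k]) + std(P[:,k])` (sample std, ddof=1 — the convention is
exposed; strict inequality, so a constant column yields an *empty*
community rather than a full one). Thresholding columns independently is
what allows overlap. A `duplicate_communities` diagnostic flags
near-identical columns, the practical symptom of choosing K too large.

**Disjoint baseline.** `modularity_partition` runs weighted Louvain
(resolution 1) from 10 seeded sweep orders and keeps the
highest-modularity partition — Louvain's greedy aggregation can stall in
local optima, and best-of-restarts is the standard remedy. On
community-structured graphs of ≤ 10 nodes the result matches exhaustive
modularity maximization exactly (tested); on dense unstructured weighted
graphs Louvain can remain suboptimal regardless of restarts, a known
limitation of the heuristic, not of the implementation.

## Graph metrics

* Degree `D_i = Σⱼ Aᵢⱼ` (weighted row sum).
* Participation coefficient `P_i = 1 − Σ_s (D_is/D_i)²` over the modules of
  a disjoint partition; `P_i ∈ [0, 1 − 1/N_m]`; zero-degree nodes are
  assigned 0 (the 0/0 case is conventionally "no participation").
* Betweenness centrality with edge lengths `1/weight` (strong edges are
  short, the convention of the standard brain-connectivity toolboxes);
  reported as raw Brandes counts summed over *ordered* source–target pairs,
  with `normalized=True` dividing by (N−1)(N−2). Published network-level
  betweenness values from specific toolboxes use unstated normalizations
  and are not reproducible from the convention alone, so only the raw
  convention is pinned by oracle tests.

## Synthetic benchmarks

`generate_timeseries` draws K i.i.d. latent signals `s_k(t) ~ N(0, σ_s²)`
and sets region i to `Σ_k m_ik s_k(t) + N(0, σ_n²)` noise, with m the
binary membership matrix (default layout: 2 overlap regions per community
pair, remaining regions dealt round-robin). Defaults σ_s = 1, σ_n = 0.3,
N = 30, T = 300, K = 3. Latent signals are white by default — the
estimators are covariance-driven, so white signals are the minimal
sufficient structure; an optional AR(1) coefficient (variance-matched)
adds fMRI-like temporal smoothness. Not emulated: haemodynamic response
convolution, scanner drift/motion artefacts, spatial noise correlations —
conclusions from these benchmarks concern covariance-structure recovery
only. `generate_adjacency` plants the block structure directly in an
adjacency matrix (within/between weight levels, ±5% seeded jitter).
Recovery is scored by greedy best-match mean Jaccard (each true community
claims its best unused found community, in index order; greedy rather than
Hungarian for simplicity and frozen so scores are stable).

### What end-to-end recovery can and cannot show

On *planted adjacencies*, where an overlap region carries full-strength
within-weights to all of its communities, the NMF stage recovers the
planted overlapping communities essentially perfectly (Jaccard 1.0 across
seeds). On *time-series generated by the additive model above*, overlap
recovery through the mean+std threshold is structurally impossible: a
region observing `s_a + s_b` has correlation ≈ `1/√(2(1+σ_n²))` ≈ 0.66
with each of its blocks, versus ≈ 0.92 within a block, so any
covariance-based estimator gives its connections at most ~0.7× the
within-block level (the l1 threshold shrinks small coefficients further,
to ~0.15× at the default penalties). Its membership loadings inherit that
ratio, while the mean+std cutoff of a 12-member column over 30 regions
sits at ~0.82× of the member level — clearing it would need a loading
ratio ≥ ~0.88, which the additive model cannot produce. Consequently the
pipeline recovers exactly the exclusive community cores (Jaccard 2/3,
stable across seeds and across solver/NMF variants) and assigns planted
overlap regions to zero communities. This is a property of the generative
model plus threshold rule, documented here rather than patched around;
the corresponding end-to-end acceptance check is left failing by design.

## Problem sizes and runtime

The test-suite and acceptance-script sizes are chosen to exercise every
code path at desk scale: oracle comparisons on T ≤ 20, N ≤ 6 instances
(where the independent Davis–Yin reference solver and exhaustive
graph-metric enumerations are exact and fast), solver contracts at
N = 30 / T ≈ 215–300, exhaustive modularity on ≤ 9-node graphs (Bell-number
enumeration), and 5-seed pipeline replicates. The full suite runs in under
a minute on one CPU; `scripts/acceptance.py` in about half a minute.

## Numerical choices

* Floating-point invariant tolerances: 1e-9 absolute unless stated;
  symmetry of adjacency matrices to 1e-12; TSV round-trip lossless to
  1e-12 (`%.17g` formatting).
* SVT accepts any SVD since the reassembled product is unique.
* Pseudo-inverse cutoff 1e-10 (relative); zero-norm columns are refused
  with the offending region named.
* NMF division guard 1e-12; KL cost treats `0·log0 = 0`.
* Seeds: every stochastic routine takes an explicit seed; restart seeds are
  `base_seed + i`.
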