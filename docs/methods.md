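# Methods

## The model and its assumptions

`bacon` treats the structural connectome as a latent symmetric binary
graph **A** over *K* regions and the probabilistic-tractography
streamline count matrix **N** as noisy evidence about it.

**Prior.** Edge presence is exchangeable across pairs: a single edge
probability *p* ~ Beta(α, β) is shared by all K(K−1)/2 unordered pairs
and integrated out, giving P(**A**) = B(e₁+α, e₀+β)/B(α, β). The
only structural knowledge encoded is therefore a soft constraint on
*global density*; edges are coupled exclusively through *p*. The prior
carries no spatial, distance, or small-world structure — every graph in
a density class is equally probable.

**Likelihood.** Conditional on **A**, the rows of **N** are independent.
Row *i* is Multinomial(S_i, **x**_i) with
**x**_i ~ Dirichlet(α_ij), α_ij = d₀(1−a_ij) + d₁a_ij over the K−1
targets j ≠ i. The Dirichlet is conjugate and is integrated out, so each
row contributes a Dirichlet-multinomial term

log P(**n**_i | **a**_i) = log S_i!/∏n_ij! + logΓ(Σα_ij) − logΓ(S_i+Σα_ij)
+ Σ_j [logΓ(n_ij+α_ij) − logΓ(α_ij)].

Assumptions worth keeping in mind: streamline counts in a row are
exchangeable given the adjacency row (no geometry, no seed-to-target
distance effects); asymmetry of **N** is pure sampling noise around a
symmetric truth; the diagonal is outside the model (inputs with nonzero
diagonals are rejected, not silently zeroed, to surface preprocessing
mistakes); S_i = 0 is legal and contributes nothing.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α, β | 14, 53 | Beta prior on density; mode (α−1)/(α+β−2) = 0.2, mean ≈ 0.209. A vague sparse-network prior. |
| d₀ | 0.01 | Dirichlet concentration off edges. Controls leakage of streamline mass onto non-edges — the expected false-positive rate. |
| d₁ | 1 | Concentration on edges. 1 is uniform over edge-restricted probability vectors, i.e. agnostic to how streamlines distribute over connections; >1 would favour even spreading, <1 winner-takes-all. |
| samples × chains | 5000 × 2 | Stored samples (one per sweep), default protocol. |
| burn-in | 0 | Initialization at the prior-mode density makes long burn-in unnecessary; configurable. |
| n_null | 100 | Density-matched random graphs for small-world normalization. |
| louvain runs | 100 | Restarts of Louvain; the best modularity is kept. |

The model requires d₀ < d₁ (equality is tolerated numerically and makes
the likelihood graph-independent, which several tests exploit; d₀ > d₁
is rejected). For a region of degree *e* among *m* + *e* targets the
expected non-edge mass is m·d₀/(m·d₀ + e·d₁); at K = 90, density 0.2
(degree 18) and d₀ = 0.01 this is 0.71/18.71 ≈ 3.8%, i.e. roughly a 5%
expected false-positive rate. `d0_calibration` tabulates both the
simulated and the closed-form value over (d₀, density) grids so the
operating point can be chosen for other parcellations.

## Inference

Metropolis proposals toggle one symmetric edge pair. The acceptance
log-ratio is the sum of a prior term — log[(e₁+α)/(e₀+β−1)] for an
addition, log[(e₀+β)/(e₁+α−1)] for a removal — and a likelihood term
touching only rows i and j: the row-sum Γ terms and the single entry's
Γ terms (multinomial coefficients cancel). Per-row concentration sums
and the total log likelihood are maintained incrementally and refreshed
from scratch every 100 sweeps to bound floating-point drift
(`SamplerState.check_consistency` asserts cache integrity in tests).
Acceptance compares log u < Δ to avoid overflow.

A sweep proposes every unordered pair exactly once in a fresh uniform
random permutation; one sample is stored per sweep. The initial state
thresholds the symmetrized counts (N + Nᵀ) to round(M·mode-density)
edges, ties at the cutoff broken uniformly at random; when the Beta mode
is undefined (α ≤ 1 or β ≤ 1) the prior mean is used instead, with a log
notice.

Chain c's RNG is spawned as SeedSequence(seed, spawn_key=(c,)), so runs
are bit-reproducible and adding chains never perturbs earlier chains'
streams. Samples are stored bit-packed by upper triangle (K = 90 ×
10⁴ samples ≈ 5 MB); archives carry a version byte and an SHA-256
checksum verified on read.

The sampler reports an acceptance rate and a split-R̂ on the edge-count
trace plus between-chain marginal agreement as convergence diagnostics;
these are this implementation's own reporting choices. Note the
acceptance rate is naturally very low once the posterior has
concentrated (most proposals try to flip confidently-decided edges), so
it is a mixing indicator only in combination with R̂.

## Graph measures and their posteriors

All measures take binary, symmetric, hollow matrices. Density is
e₁/M. Clustering is the average nodal transitivity with degree < 2
contributing 0. Characteristic path length averages BFS distances over
ordered *reachable* pairs; if any pair is unreachable a `disconnected`
flag is returned alongside the value, and `MetricPosterior` records the
fraction of disconnected samples — nothing is silently dropped.
Betweenness uses Brandes accumulation normalized by (K−1)(K−2) ordered
pairs so values lie in [0, 1]. Modularity is the best Newman–Girvan Q
over repeated Louvain runs (resolution fixed at 1). Louvain and
betweenness are delegated to networkx behind these interfaces.

Small-worldness is σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) where the null
statistics are *means* over uniform random graphs with identical node
and edge counts ("density-matched"; not degree-preserving rewiring).
Null sets are cached keyed by (K, e₁, n_null) and shared across
posterior samples and the thresholded baseline so normalizations are
comparable. Null graphs are not forced to be connected; their path
length, like the graph's own, averages over reachable pairs.

The 95% HPD interval is the shortest contiguous window of order
statistics containing ⌈0.95·n⌉ draws, ties broken toward the smallest
lower bound. Only this contiguous definition is provided; strongly
multimodal posteriors would be summarized conservatively by one wide
interval rather than split intervals.

## Baseline and comparison statistics

The point-estimate baseline symmetrizes counts and keeps either the top
m pairs (`threshold_to_edge_count`, ties uniform at random; m is
typically round(mean posterior edge count)) or all pairs with weight ≥ t
(`threshold_at_count`). The per-region centrality distance is
z_i = (point betweenness − posterior median)/posterior SD, with zero-SD
entries flagged NaN; a helper takes the median of z_i across subjects.
Group-level edge differences average thresholded graphs and posterior
probability matrices over subjects, take the difference on every pair
non-zero in either mean, and Z-standardize those differences (default
report threshold |Z| > 2.3); subject inputs must already be aligned —
mismatched region labels are an error, not a reorder.

## Synthetic data

`generate_fixture` forward-simulates complete datasets with known
ground truth: presets tiny (K=4, S=20; the posterior is enumerable over
64 graphs), small (K=12, S=1000), medium (K=30, S=5000) and atlas_scale
(K=90). The ground-truth graph is drawn uniformly among graphs at
exactly the prior-mode density (0.2 under the default prior) rather
than from the Beta-Binomial itself, so every preset's density condition
holds exactly and run-to-run comparisons are not confounded by density
drift; counts then follow the generative model.

What the generator emulates: asymmetric counts from a symmetric truth,
per-region streamline budgets, d₀-controlled false-positive leakage.
What it does not: geometric or distance-dependent streamline bias,
spatially correlated seeding artifacts, inter-subject variability, or
model misspecification of any kind — passing recovery tests shows the
inference machinery is correct *under the model*, not that the model
captures real tractography.

## Numerical choices

- All probabilities in log space via `lgamma`/`gammaln`/`betaln`; no
  factorials or Beta functions evaluated directly (S_i up to 10⁷).
- The multinomial coefficient is computed only for absolute
  log-likelihood values; ratios omit it (it cancels).
- One uniform variate is consumed per proposal whether or not Δ ≥ 0,
  keeping RNG streams aligned across parameterizations.
- Degenerate inputs: S_i = 0 rows contribute 0; empty graphs are
  rejected by modularity and path length with clear messages; the
  complete graph's small-worldness is exactly 1 (its only
  density-matched null is itself).
- Validation sizes: exactness checks against enumeration use K = 4
  (64 graphs, 2 × 4000 sweeps); likelihood normalization enumerates all
  27 count matrices at K = 3, S = (2,2,2); parameter recovery uses
  K = 30 with 2 × 200 sweeps, which the strong S_i = 5000 signal makes
  ample. These sizes keep the full validation suite and the acceptance
  script each well under a minute while leaving the checks sharp.

## Known limitations

- The posterior is over *binary* graphs; connection strengths are not
  modelled.
- d₀ and d₁ are fixed and shared across subjects; no hyper-prior.
- Single-pair toggle proposals only — no tempering or exchange moves —
  so mixing on strongly multimodal posteriors (rare under strong data)
  is not accelerated.
- Graph measures on disconnected samples follow the reachable-pairs
  convention; compare across methods only with the same convention.
- Inference cost grows as O(M) per sweep with O(1) per proposal;
  K = 90 with the full 2 × 5000 protocol takes a few minutes, finer
  parcellations scale quadratically in K.
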