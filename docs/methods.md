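# Methods

## Scope and data model

The pipeline starts from an integer OTU × sample count table (the output
of upstream read processing and 97% clustering, which is out of scope) and
a sample-to-group map. Samples are columns; all operations treat OTU ids
and sample ids as opaque strings. The analysis order is: rarefaction →
alpha diversity; rarefaction → Bray–Curtis → PCoA/ANOSIM; rarefaction →
Spearman matrix → thresholded network → topology, modules, node roles.

## Synthetic communities

The generator's purpose is ground truth: every downstream stage can be
scored against known structure.

**Model.** Counts come from a Gaussian copula. A latent vector per sample
is multivariate normal with block-diagonal correlation: each planted
module is an equicorrelated block at `intra_correlation` (drawn as
z = √r·f + √(1−r)·e with a shared factor f per module), off-block zero.
The latent normal CDF values are pushed through each OTU's
negative-binomial quantile function. The NB mean of OTU *i* in sample *j*
is *aᵢ·dⱼ·gᵢⱼ*, with *a* a log-normal(σ = 1.5) baseline relative-abundance
profile normalized to 1 (long-tailed, as amplicon OTU abundance
distributions are), *dⱼ* the sample's target depth
(normal with mean `depth_mean`, CV `depth_cv`, floored at 1), and *gᵢⱼ* a
group fold change e^`group_effect` applied to a `group_effect_fraction`
of OTUs per group (disjoint sets across groups while OTUs remain).
Variance is m + φm² with φ = `dispersion` (default 0.2, moderate amplicon
overdispersion). Rank-based downstream statistics depend only on the
copula, so planted latent correlation translates into planted Spearman
correlation up to count discretization (ties at low counts attenuate it).

**Defaults.** Three groups ("FP", "DI", "MF") mirroring a three-treatment
irrigation design, but 10 replicates per group rather than the field
experiment's 3: a two-sided Spearman P < 0.01 is unattainable at n = 3, so
network experiments need more samples (`spearman_matrix` refuses n < 4 and
warns below n = 10). Depth 50 000 reads with CV 0.1, the order of
published *amoA* rarefaction depths. All draws derive from one seed via
per-stage `SeedSequence` substreams, so datasets are bitwise reproducible.

**What it does not emulate.** No compositional closure at generation time
(counts are independent NB given the copula), no taxonomic structure, no
chimeras/clustering noise, no spatial or temporal autocorrelation among
replicate plots. Passing recovery tests therefore shows the inference
chain is correct and well calibrated on overdispersed count data with
known rank structure — not that a field survey at n = 3 would support the
same inference.

**Closure effects worth knowing.** Rarefaction (or any total-sum scaling)
makes counts compositional. Two consequences observed with this generator
and accounted for in the tests: (i) under full independence, samples
dominated by one abundant OTU show a small spurious positive Spearman
correlation among the remaining OTUs after rarefaction (~+0.1), so the
copula's independence property is asserted on raw counts; (ii) when a
single correlated block spans a large share of the community, dividing by
the total cancels the shared factor and can erase the block's rank signal.
With realistic module shares (e.g., 4 modules of 6 among 40 OTUs) both
effects are negligible and recovery from rarefied counts is near perfect.

## Rarefaction and alpha diversity

Rarefaction draws each sample's subsample of exactly `depth` reads without
replacement (multivariate hypergeometric), seeded. One draw by default —
matching the common one-shot "subsample to the shallowest sample"
convention — with averaging over `n_iterations` draws available. All-zero
OTU rows are retained; dropping them is an explicit separate step.
Requesting a depth above any sample's total is an error naming the sample.

Shannon is computed in nats (the base is not standardized in the
literature; `--log-base` exposes 2 and 10). Chao1 uses the classic
singleton/doubleton form when F₂ > 0 and the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) when F₂ = 0, keeping the estimate finite;
the estimate is always ≥ observed richness.

## Beta ordination

Bray–Curtis is computed on counts (rarefied first in the CLI pipeline, so
all samples are at even depth); an all-zero sample is a domain error.
PCoA double-centers the squared distances and eigendecomposes;
coordinates use only positive eigenvalues (tolerance 10⁻¹² relative to
the largest), so Euclidean-embeddable inputs are reconstructed exactly.
Negative eigenvalues — routine for Bray–Curtis — are reported untouched;
no correction is applied by default because published workflows rarely
state one, with the Lingoes correction behind a flag.
`proportion_explained` normalizes positive eigenvalues to sum to 1.

ANOSIM ranks all n(n−1)/2 distances with average ranks on ties (sparse
tables tie often) and uses Clarke's statistic
R = (r̄_between − r̄_within)/(n(n−1)/4), which lives in [−1, 1] and hits 1
exactly when every between-group distance exceeds every within-group
distance. Group labels are permuted uniformly (seeded, default 999
permutations) and the p-value is the inclusive estimator
(1 + #{R_perm ≥ R_obs})/(1 + n_permutations), so p ≥ 1/(n_perm+1) and the
test is exact-level by construction. Measured type-I error over 200 null
communities is ~0.05.

## Co-occurrence networks

**Correlation.** Spearman ρ is Pearson correlation of average-ranked
abundance profiles; two-sided p-values use the t-approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df, with p = 0 pinned at |ρ| = 1. Constant
OTUs (rank variance zero) are dropped with a logged warning; a prevalence
filter is available but defaults to keeping all OTUs. No multiple-testing
correction by default — the conventional raw P < 0.01 screen — and an
exact permutation p-value (`spearman_exact_pvalue`) exists for n ≤ 8,
where the t-approximation is unreliable.

**Thresholding.** An edge requires |ρ| > 0.7 AND p < 0.01, both strict, so
ρ = 0.7 exactly is rejected. Both signs qualify by default (strong
negative correlations are as informative as positive ones);
`positive_only` reproduces a sign-restricted reading. Nodes are OTUs with
at least one retained edge — isolated OTUs are excluded, so node counts
describe the drawn network. An empty network is a valid result.

**Topology.** Average degree, edge density and linkage density
("complexity") are exact functions of N and E (2E/N, 2E/(N(N−1)), E/N).
Average path length is the mean unweighted shortest path over connected
pairs, i.e. a within-component average — co-occurrence graphs are
routinely multi-component, and this is the convention of common network
tools; a largest-component mode is available. Clustering is the mean
local clustering coefficient with degree-<2 nodes contributing 0.
Modularity is Newman's Q of the supplied partition; Q of the one-module
partition is identically 0. An empty network reports NaN metrics rather
than zeros.

**Modules.** Louvain modularity maximization at resolution 1.0, seeded,
via networkx; labels are canonicalized by decreasing module size (ties by
smallest member id) so a fixed seed yields fixed labels.

**Node roles.** Zᵢ standardizes within-module degree against the node's
own module (population SD; Zᵢ = 0 when the SD is 0 — identical nodes are
not hubs). Pᵢ = 1 − Σₛ(k_is/kᵢ)² over all modules the node touches, hence
Pᵢ ≤ 1 − 1/m for a node touching m modules. Roles cut at Zᵢ = 2.5 and
Pᵢ = 0.62 with boundary values assigned to the lower category (the
hub/connector conditions are strict inequalities).

## Problem sizes and numerical choices

Validation experiments use: 50-sample communities with 4 planted modules
of 6 OTUs among 40 for recovery scoring; 200 null communities × 999
permutations for ANOSIM calibration; 1000 random 8-sample pairs against
the brute-force rank formula (agreement to 10⁻¹²); 15-point Euclidean
configurations for PCoA reconstruction (10⁻⁸). These sizes give stable
statistics while keeping a full run to seconds. Correlation matrices are
clipped to [−1, 1] and symmetrized after the rank-Pearson step to absorb
floating-point asymmetry; serialized correlations carry 6 decimals.

## Known limitations

- Spearman screening on relative or rarefied counts ignores
  compositionality; SparCC/CCLasso-style inference is explicitly out of
  scope.
- The t-approximation p-value is anti-conservative at very small n; the
  package warns below n = 10 rather than silently proceeding.
- Per-treatment networks from 3 replicate plots cannot clear P < 0.01;
  the correlation stage refuses n < 4 by design, so study-scale designs
  must pool samples or add replicates before network inference.
- Louvain is a stochastic heuristic; results are reproducible only at a
  fixed seed, and modularity values are partition-dependent.
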