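# Methods

This note documents the models and procedures implemented in `cohortnet`,
the parameter choices that matter, and what the synthetic benchmarks do and
do not demonstrate.

## The synthetic community model

The generator (`cohortnet.synthetic`) emulates the statistical structure of
large 16S amplicon surveys along an environmental gradient. For member *i* of
cohort *g* in sample *s* at gradient value *x_s*:

    E[abundance] = a_g(x_s) · w_i · ε_is,    a_g(x) = exp(−(x − μ_g)² / (2 σ_g²))

with member base weights w_i ~ lognormal(0, `member_weight_sigma`) and
per-sample per-ASV noise ε_is ~ lognormal(0, `sample_noise_sigma`).
Background ASVs have gradient-independent expectation
`background_scale · w_i · ε_is`. Reads are drawn multinomially per sample
from the closed (renormalized) expectations at a lognormal sequencing depth,
so row sums equal the drawn depths exactly and the compositional constraint
is explicit. Gradient values are evenly spaced over `gradient_range`.

Default condition (used throughout the tests): 300 samples over a
temperature-like gradient of 0–30 units, 6 cohorts × 40 members, 60
background ASVs (20% of features), `member_weight_sigma = 1.0`,
`sample_noise_sigma = 0.6`, median depth 20 000 (σ = 0.3),
`background_scale = 0.25` (≈ 10–25% of reads in the background pool).

**Niche geometry.** Niche optima default to the midpoints of an even
partition of the gradient (2.5, 7.5, …, 27.5) with a common width σ = 1.5,
i.e. neighbouring optima are more than 3 SD apart — cohorts with genuinely
*distinct* optima. This is a deliberate design point: when niche widths
approach the optimum spacing (σ ≳ 2 at spacing 5), neighbouring cohorts
co-occur across broad gradient bands and their members are *correctly*
linked by positive co-occurrence, so no clustering method can (or should)
separate them. The width is a config field; the test suite exercises the
distinct-optimum regime.

Two additional fixtures derive from the same machinery: a **null community**
(independent lognormal expectations, no cohort structure — the type-I-error
fixture) and **paired datasets** sharing a configurable fraction of cohorts
with identical ASV identifiers and member weights (the compositional-
stability fixture).

What the generator does *not* emulate: phylogenetic relatedness, negative
interactions (only positive co-occurrence is analysed downstream), spatial
autocorrelation, multi-dimensional niches, and the extreme sparsity of very
large surveys. Passing the planted-recovery tests therefore shows the
pipeline recovers gradient-driven co-variation from compositional counts; it
does not certify performance on data whose structure is dominated by those
unmodelled features.

## Correlation inference

**SparCC.** Counts are converted to fractions by Dirichlet resampling
(posterior draw with a uniform prior, via normalized gamma variables). From
the log-fraction covariance we form the variation matrix
t_ij = Var(ln x_i/x_j) and solve the sparsity approximation
Σ_j t_ij ≈ (p − 2) ω_i² + Σ_j ω_j² for the basis variances ω² (negative
solutions are clamped to 10⁻¹⁰). Basis correlations follow as
ρ_ij = (ω_i² + ω_j² − t_ij) / (2 ω_i ω_j), clipped to [−1, 1]. The most
strongly correlated pair with |ρ| above the exclusion threshold (default
0.1) is then removed from the linear system and the solve repeated, up to 50
exclusion rounds per iteration; an ASV is never excluded down to fewer than
two remaining pairs, keeping the system well posed. The final estimate is
the elementwise median over 20 estimation iterations. All knobs are exposed;
the defaults are the conventional ones.

**clr-Pearson.** Pearson correlation between centred-log-ratio transformed
ASV vectors, with a pseudocount of 1 on counts (the simplest zero handling;
configurable). Zero-variance columns yield correlation 0 and are flagged.

**Bootstrap p-values.** Each bootstrap permutes every ASV's count vector
across samples independently — a correlation-free null that preserves every
marginal — and re-estimates the correlation matrix with the same method and
settings. p_ij is the proportion of bootstrap values ≥ the observed r_ij
(one-sided, positive tail, since only positive co-occurrences become edges).
Under the null fixture these p-values are uniform (KS < 0.02 in practice).
No multiplicity correction is applied by default — the standard practice for
this analysis is a raw P ≤ .05 cut — but a Benjamini–Hochberg option exists
on `build_network(fdr_bh=True)`.

**Network rule.** Edge iff r > r-threshold (strict), P ≤ .05, r > 0;
isolated nodes dropped. Standard thresholds are r = 0.25 (inclusive) and
r = 0.4 (conservative). An adapter (`network_from_edge_list`) accepts
externally inferred edge lists (e.g. from conditional-independence methods
that output unweighted graphs) so the verification grid remains runnable
with a third method; such methods are otherwise out of scope here.

## Consensus clustering

Leiden (modularity objective on edge weights, RB resolution parameter γ) is
run `reps_per_resolution = 10` times at each of 20 γ values log-spaced over
[0.3, 2.0]. Pairwise co-classification frequencies are computed; pairs with
frequency ≥ 0.5 form a weighted consensus graph which is re-clustered with
the same ensemble, iterating (≤ 5 rounds) until the co-classification matrix
is binary — the partition is then its connected components. If the loop does
not converge, a single Leiden pass at γ = 1 on the final consensus graph is
the fallback (not observed in practice on modular inputs). Reported Q is
always the γ = 1 weighted Newman modularity on the *original* network.

The **mean resolution** handed to the attack analysis is the average of grid
γ values whose first-round partitions agree with the consensus at mean
ARI ≥ 0.9, falling back to the grid mean if none qualify. This automates the
"select a stable resolution plateau" step; both the grid and the ARI cutoff
are parameters, so a manual override is a one-line config change.

Walktrap (4-step walks, max-modularity cut) serves the r-threshold
sensitivity sweep; Clauset–Newman–Moore greedy agglomeration serves the null
models, where its merge dendrogram is cut at a prescribed cluster number k
(a disconnected graph cannot merge below its component count; the component
count is used in that degenerate case).

Modularity is computed directly as Q = Σ_c (W_c/W − (S_c/2W)²) and checked
in the tests against an O(n²) pair-sum oracle at 10⁻¹⁰.

## Null models and resilience

**Rewiring** randomizes a network by double-edge swaps — 10 × node-count
*attempted* swaps by default (a count-successful-swaps mode exists); swaps
creating self-loops or multi-edges are rejected. Weights travel with their
edge slot, so node set, degree sequence, edge count and the weight multiset
are all conserved (asserted on every call).

**Modularity significance**: 500 rewired networks, each re-clustered
greedily at the observed cluster number; the empirical p is the raw
proportion of null modularities ≥ observed (ties favour the null). The raw
proportion can be exactly 0 — that is how "p < 1/500" is expressed; a
smoothed (b+1)/(B+1) variant is available behind a flag.

**Attack resilience**: for removal fractions 0–0.8 in steps of 0.05, random
node subsets are removed (50 bootstraps per fraction by default), the
surviving subgraph is re-clustered with Leiden at the consensus mean
resolution, and agreement with the reference partition restricted to the
survivors is scored by ARI. The rewired arm applies the same attack to 50
rewired instances, each scored against its *own* greedy partition at matched
k (the natural reference for a randomized network; scoring against the
observed partition mapped onto the rewired graph would conflate rewiring
loss with attack loss). The per-fraction mean ARI difference
(observed − rewired) is the resilience statistic; positive values mean the
cohort structure survives extinctions better than degree-matched chance.
Draws leaving fewer than 3 nodes or an edgeless subgraph are NaN-coded.

## Cohort metrics, stability and ecology

- **Mapped counts**: fraction of reads on cohort-member ASVs, per sample.
- **Effective cohort number**: inverse Simpson 1/Σ q_c² on cohort-mapped
  reads renormalized per sample (a flag can include an "unassigned"
  pseudo-cohort in the denominator instead).
- **Cohort profiles**: mean member-ASV relative abundance per cohort,
  renormalized within the cohort (whole-community scale via a flag);
  cross-dataset comparison aligns profiles on the union of exact ASV
  identifiers and uses Bray–Curtis similarity 1 − Σ|x−y|/Σ(x+y).
- **Cluster-clusters**: Ward linkage on Bray–Curtis dissimilarities in the
  "ward.D" convention — the Lance–Williams update runs on the dissimilarities
  as given, implemented by feeding their square roots to the squared-input
  linkage (identical merge order; heights are a monotone transform, which
  leaves cluster cuts and silhouettes unchanged). Group count k maximizes
  mean silhouette width over k = 2…n−1.
- **Environmental preferences**: abundance-weighted means of each variable
  per cohort, z-scored across cohorts per variable (population SD, so
  columns have exactly mean 0 / SD 1).
- **PERMANOVA**: Anderson-style partition of the Gower-centred matrix of the
  Bray–Curtis distances against numeric predictors; sequential terms by
  default (SS and R² then sum exactly to the total; a marginal mode is
  available), pseudo-F per term against the residual, p by sample
  permutation with the observed statistic included in numerator and
  denominator. The environmental "Euclidean distance" enters through the
  standardized predictor design — the standard reading of this analysis — and
  is cross-checked in the tests against an independent one-way
  implementation.
- **Sample-wise modularity**: the network restricted to the ASVs present in
  a sample, scored with the full-network cohort labels; edgeless subgraphs
  are NaN. Declines at gradient extremes (tested via outer vs middle
  deciles, the operationalization of "extremes") signal dominance by fewer
  cohorts; a cubic OLS fit on the centred/scaled gradient summarizes the
  trend.

## Numerical and design choices

- All randomness flows through explicit integer seeds; the pipeline derives
  per-stage seeds from a single master seed via `SeedSequence`, recorded in
  the run manifest.
- Feature filter semantics: prevalence first, abundance top-up only to reach
  the floor ("fallback"); a "union" mode always keeps the top-abundance set
  as well. Presence means count > 0 — no detection threshold.
- Partition labels are canonicalized (1…k by decreasing size), making
  outputs invariant to node ordering.
- Empty networks are explicit, non-crashing results; every downstream stage
  rejects them with a clear error.
- Problem sizes in the test suite (200-replicate bootstraps in the shared
  planted-community fixture, 20-replicate attack bootstraps, 100-bootstrap
  null-community checks) are reduced relative to the 500/50 production
  defaults; they are chosen so the tested contrasts are decisive at a few
  percent Monte-Carlo error while keeping the suite fast enough to run on
  every change. The acceptance script uses the full 500/500 production
  settings.

## Known limitations

- SparCC's sparsity assumption biases estimates when many pairs are strongly
  correlated; the exclusion heuristic mitigates but does not remove this.
- The clr pseudocount induces shared "absence" signal among ASVs that are
  jointly missing from many samples; with strongly overlapping niches this
  genuinely links neighbouring cohorts (see niche geometry above).
- The consensus procedure assumes the network has a meaningful modular
  decomposition somewhere in the resolution grid; on unstructured graphs the
  stability-plateau rule falls back to the grid mean.
- PERMANOVA uses numeric predictors with one df each; factors must be coded
  by the caller.
- Cross-dataset profile alignment is by exact ASV identifier — no sequence
  clustering or taxonomy-based matching.
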