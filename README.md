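# cohortnet

Inference and ecological validation of **microbial cohorts** — clusters in
co-occurrence networks built from 16S rRNA amplicon count tables — for
microbial ecologists who want to go beyond "the network is modular" and ask
whether the modules are ubiquitous, stable and environmentally meaningful
units.

## What it does

Given a samples × ASVs count table, the pipeline:

1. **Filters features**: keeps every ASV present in ≥ 10% of samples, topping
   up with the most abundant ASVs so at least 5000 survive (both knobs
   configurable), and reports the fraction of reads retained.
2. **Estimates compositional correlations** between ASVs, either with
   **SparCC** (Dirichlet-resampled fractions, log-ratio variances
   t_ij = Var(ln x_i/x_j), a sparse linear solve for basis variances ω_i²,
   ρ_ij = (ω_i² + ω_j² − t_ij)/(2ω_iω_j), iterative exclusion of strongly
   correlated pairs, median over 20 estimation iterations) or with **Pearson
   correlation of clr-transformed counts**.
3. **Attaches bootstrap p-values**: each of 500 bootstrap iterations permutes
   every ASV's counts across samples independently and re-estimates the
   correlations; p_ij is the one-sided (positive tail) exceedance proportion.
4. **Builds the co-occurrence network**: edges are pairs with r above a
   chosen r-threshold (0.25 or 0.4 in standard use), bootstrap P ≤ .05 and
   r > 0; isolated nodes are dropped.
5. **Clusters it into cohorts** with a multi-resolution **Leiden consensus**:
   Leiden is run repeatedly across a resolution grid, co-classification
   frequencies are thresholded into a consensus graph, and the procedure
   iterates until the partition is stable.
6. **Validates the cohorts**:
   - modularity significance against 500 degree-preserving rewired null
     networks re-clustered at the matched cluster number (empirical p),
   - node-removal **attack resilience** scored by adjusted Rand index against
     the same attacks on rewired networks,
   - per-sample cohort metrics (mapped counts, richness, inverse-Simpson
     effective cohort number),
   - cross-dataset compositional stability via Bray–Curtis similarity of
     cohort profiles, Ward/silhouette grouping into "cluster-clusters",
   - ecology: cohort abundances, log-ratio trends along environmental
     gradients, abundance-weighted environmental preference z-scores,
     PERMANOVA, and per-sample modularity along gradients.

A synthetic community generator with **planted cohort structure** (Gaussian
niche responses along an environmental gradient, lognormal weights and noise,
multinomial sampling at lognormal depth) provides exact ground truth, so the
whole pipeline is testable without downloading any data.

## Worked example

```python
import cohortnet as cn

table, metadata, truth = cn.generate_community(cn.GeneratorConfig(seed=0))
est = cn.pearson_clr_correlations(table)
cn.bootstrap_pvalues(table, est, n_boot=500, seed=1)
net = cn.build_network(est, r_threshold=0.25)
res = cn.consensus_partition(net, seed=2)
sig = cn.modularity_significance(net, res.partition, n_iter=500, seed=3)

print(net)
print("cohorts:", res.partition.n_clusters, " modularity Q =", round(res.partition.modularity, 3))
print("empirical p =", sig.empirical_p, " max null Q =", round(sig.null_Q.max(), 3))
print("mean mapped fraction =", round(cn.mapped_count_fraction(table, res.partition).mean(), 3))
```

prints

```
CoNetwork(284 nodes, 4961 edges)
cohorts: 7  modularity Q = 0.822
empirical p = 0.0  max null Q = 0.28
mean mapped fraction = 0.902
```

Reading: of the 300 simulated ASVs, 284 carry at least one significant
positive co-occurrence at r > 0.25; the consensus finds 7 cohorts (the six
planted ones plus the co-varying background pool) with modularity Q = 0.822;
none of 500 degree-matched rewired networks reaches that modularity
(empirical p = 0, i.e. p < 1/500 — the null never exceeds Q ≈ 0.28); and 90%
of all reads map to a cohort member.

The same pipeline is available from the shell, driven by a YAML config:

```bash
cohortnet simulate --config cfg.yaml      # or point counts_path at your TSV
cohortnet filter   --config cfg.yaml
cohortnet infer    --config cfg.yaml
cohortnet network  --config cfg.yaml --sensitivity
cohortnet cluster  --config cfg.yaml
cohortnet significance --config cfg.yaml
cohortnet attack   --config cfg.yaml
cohortnet metrics  --config cfg.yaml
cohortnet ecology  --config cfg.yaml
cohortnet all      --config cfg.yaml      # everything in one go
```

Every stage writes plain TSV/GraphML/JSON outputs plus a manifest with all
parameters and per-stage seeds, sufficient to reproduce any run bit-for-bit.

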