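"""Stagewise cohort-inference pipeline with deterministic seeding.

``run_pipeline`` executes the stages in order -- input (load or simulate),
feature filter, correlation inference with bootstrap p-values, network
construction, consensus clustering, modularity significance, cohort metrics,
and (when configured) attack resilience and ecology -- writing every stage's
output to the output directory in plain formats (TSV / GraphML / JSON) plus a
manifest recording parameters and the per-stage seeds, so any run can be
reproduced bit-for-bit.  Each stage can also be re-run from its cached
predecessors through the CLI.  ``run_verification`` re-infers cohorts on
random sample subsets and reports cross-trial agreement (ARI), compositional
similarity to the gold-standard trial and gradient slopes per trial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import Partition, consensus_partition
from .cohorts import cohort_metrics_frame, cohort_profile, cohort_sizes, \
    cross_trial_agreement
from .cooccurrence import CorrelationEstimate, bootstrap_pvalues, \
    pearson_clr_correlations, sparcc_correlations
from .ecology import cohort_abundance, cohort_log_ratio, \
    gradient_correlation, environmental_preference, sample_modularity
from .io import CountTable, SampleMetadata, filter_features, read_count_table
from .network import build_network
from .nullmodels import attack_vs_rewired, modularity_significance
from .synthetic import GeneratorConfig, generate_community
from .cohorts import bray_curtis_similarity, _aligned_matrix

__all__ = ["PipelineConfig", "run_pipeline", "run_verification",
           "stage_seed", "read_correlation_tsv"]

# fixed per-stage seed channels, spawned from the master seed
_STAGE_CHANNELS = {"simulate": 0, "infer": 1, "bootstrap": 2, "cluster": 3,
                   "significance": 4, "attack": 5, "verify": 6}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_CHANNELS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Declarative configuration for the full pipeline.

    Defaults mirror the standard analysis settings: prevalence filter at 10%
    with a 5000-ASV abundance floor, SparCC with 20 estimation iterations,
    500 bootstrap iterations for edge p-values (excluded at P > .05),
    r-threshold 0.25 or 0.4 (0.4 default here), 500 rewired nulls for
    modularity significance, and 50x50 bootstrapped node-removal attacks over
    removal fractions 0-0.8.
    """

    # input: either a counts TSV (+ optional metadata) or a simulation
    counts_path: str | None = None
    orientation: str = "samples_as_rows"
    metadata_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # feature filter
    prevalence_min: float = 0.10
    min_keep: int = 5000
    filter_mode: str = "fallback"
    # correlation inference
    method: str = "sparcc"  # or "pearson_clr"
    n_estimate_iter: int = 20
    n_exclusion_iter: int = 50
    exclusion_threshold: float = 0.1
    pseudocount: float = 1.0
    n_boot: int = 500
    # network thresholds
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    # consensus clustering
    resolution_grid: list | None = None
    reps_per_resolution: int = 10
    # null models
    n_null_iter: int = 500
    run_attack: bool = False
    attack_fractions: list | None = None
    attack_n_boot: int = 50
    attack_n_rewired: int = 50
    # ecology
    env_variables: list | None = None
    log_ratio_pair: list | None = None  # [cohort_a, cohort_b]; None = auto
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        cfg = cls(**{k: v for k, v in d.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if gen is not None:
            if isinstance(gen, dict):
                if "gradient_range" in gen and gen["gradient_range"] is not None:
                    gen["gradient_range"] = tuple(gen["gradient_range"])
                cfg.generator = GeneratorConfig(**gen)
            else:
                cfg.generator = gen
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_correlation_tsv(r_path, p_path=None, method="sparcc") -> CorrelationEstimate:
    """Rehydrate a CorrelationEstimate from square TSV matrices."""
    r = pd.read_csv(r_path, sep="\t", index_col=0)
    p = pd.read_csv(p_path, sep="\t", index_col=0).to_numpy() if p_path else None
    return CorrelationEstimate(asv_ids=list(r.index), r=r.to_numpy(), p=p,
                               method=method)


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    if config.counts_path is not None:
        table = read_count_table(config.counts_path, config.orientation)
        metadata = (SampleMetadata.read_tsv(config.metadata_path)
                    if config.metadata_path else None)
        truth = None
    else:
        gen = dataclasses.replace(
            config.generator, seed=stage_seed(config.seed, "simulate"))
        table, metadata, truth = generate_community(gen)
        table.write_tsv(outdir / "counts.tsv")
        metadata.write_tsv(outdir / "metadata.tsv")
        truth.to_json(outdir / "truth.json")
    return table, metadata, truth


def _infer(config: PipelineConfig, table: CountTable) -> CorrelationEstimate:
    if config.method == "sparcc":
        est = sparcc_correlations(
            table, n_estimate_iter=config.n_estimate_iter,
            n_exclusion_iter=config.n_exclusion_iter,
            exclusion_threshold=config.exclusion_threshold,
            seed=stage_seed(config.seed, "infer"))
    elif config.method == "pearson_clr":
        est = pearson_clr_correlations(table, pseudocount=config.pseudocount)
    else:
        raise ValueError(f"unknown inference method {config.method!r}")
    bootstrap_pvalues(table, est, n_boot=config.n_boot,
                      seed=stage_seed(config.seed, "bootstrap"))
    return est


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the in-memory result bundle.

    Outputs land in ``config.outdir``; the manifest records package version,
    parameters and per-stage seeds.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = []

    def note(stage, msg):
        log.append(f"[{stage}] {msg}")

    table, metadata, truth = _load_or_simulate(config, outdir)
    note("input", f"{table.n_samples} samples x {table.n_asvs} ASVs")

    filtered, report = filter_features(table, config.prevalence_min,
                                       config.min_keep, config.filter_mode)
    filtered.write_tsv(outdir / "filtered_counts.tsv")
    report.to_json(outdir / "filter_report.json")
    note("filter", f"{report.n_asvs_after}/{report.n_asvs_before} ASVs kept, "
         f"{report.reads_retained_fraction:.3f} reads retained")

    estimate = _infer(config, filtered)
    estimate.write_tsv(outdir / "correlation.tsv", outdir / "pvalues.tsv")
    note("infer", f"method={config.method}, n_boot={config.n_boot}")

    network = build_network(estimate, config.r_threshold, config.p_threshold)
    if network.is_empty:
        raise RuntimeError(
            "network stage produced an empty network "
            f"(r_threshold={config.r_threshold}); nothing to cluster")
    network.write_graphml(outdir / "network.graphml")
    network.write_edgelist_tsv(outdir / "edges.tsv")
    note("network", f"{network.n_nodes} nodes, {network.n_edges} edges "
         f"at r>{config.r_threshold}, p<={config.p_threshold}")

    consensus = consensus_partition(
        network, grid=config.resolution_grid,
        reps_per_resolution=config.reps_per_resolution,
        seed=stage_seed(config.seed, "cluster"))
    partition = consensus.partition
    partition.write_tsv(outdir / "partition.tsv")
    (outdir / "consensus.json").write_text(json.dumps(consensus.summary()))
    note("cluster", f"{partition.n_clusters} cohorts, Q={partition.modularity:.3f}, "
         f"mean_resolution={consensus.mean_resolution:.3f}")

    significance = modularity_significance(
        network, partition, n_iter=config.n_null_iter,
        seed=stage_seed(config.seed, "significance"))
    (outdir / "significance.json").write_text(json.dumps(significance.summary()))
    note("significance", f"p={significance.empirical_p:.4g} "
         f"({significance.n_iter} rewired nulls, k={significance.k_matched})")

    metrics = cohort_metrics_frame(filtered, partition)
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    sizes = cohort_sizes(partition)
    note("metrics", f"cohort sizes: {sizes}")

    attack = None
    if config.run_attack:
        attack = attack_vs_rewired(
            network, partition, consensus.mean_resolution,
            fractions=config.attack_fractions, n_boot=config.attack_n_boot,
            n_rewired=config.attack_n_rewired,
            seed=stage_seed(config.seed, "attack"))
        attack.to_long_frame().to_csv(outdir / "attack.tsv", sep="\t", index=False)
        (outdir / "attack.json").write_text(json.dumps(attack.summary()))
        note("attack", "ARI difference per fraction: "
             + np.array2string(np.asarray(attack.ari_difference), precision=3))

    ecology = None
    if metadata is not None:
        ecology = _run_ecology(config, filtered, metadata, network, partition,
                               outdir, note)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_CHANNELS},
        "log": log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {"table": table, "filtered": filtered, "filter_report": report,
            "metadata": metadata, "truth": truth, "estimate": estimate,
            "network": network, "consensus": consensus, "partition": partition,
            "significance": significance, "metrics": metrics, "attack": attack,
            "ecology": ecology, "manifest": manifest}


def _run_ecology(config, table, metadata, network, partition, outdir, note):
    variables = config.env_variables or [
        c for c in metadata.variables
        if pd.api.types.is_numeric_dtype(metadata.to_dataframe()[c])]
    if not variables:
        return None
    meta = metadata.aligned_to(table.sample_ids, strict=False)
    abund = cohort_abundance(table, partition)
    abund.to_csv(outdir / "cohort_abundance.tsv", sep="\t",
                 index_label="sample_id")
    out = {"variables": variables}

    if abund.shape[1] >= 2:
        pref = environmental_preference(abund, meta, variables)
        pref.z.to_csv(outdir / "preference_zscores.tsv", sep="\t",
                      index_label="cohort")
        out["preference"] = pref
        # log-ratio of the two most abundant cohorts against the first variable
        pair = config.log_ratio_pair or list(
            abund.sum(axis=0).sort_values(ascending=False).index[:2])
        lr = cohort_log_ratio(abund, pair[0], pair[1])
        fit = gradient_correlation(lr, meta[variables[0]])
        out["log_ratio_pair"] = pair
        out["gradient_fit"] = fit
        note("ecology", f"log-ratio {pair} vs {variables[0]}: "
             f"r={fit.r:.3f}, slope={fit.slope:.3f}")

    sq = sample_modularity(network, partition, table)
    sq.rename_axis("sample_id").to_csv(outdir / "sample_modularity.tsv", sep="\t")
    out["sample_modularity"] = sq
    return out


def run_verification(config: PipelineConfig, subset_fractions=(0.5, 0.7),
                     n_trials_per_fraction: int = 1) -> dict:
    """Cohort robustness against subsampling: re-infer on random subsets.

    The gold standard is the full-data run.  Every subset (and the full data)
    is restricted to the ASVs present in all trials, then inferred and
    clustered with the configured method.  Reports the pairwise cross-trial
    ARI matrix, each trial's mean Bray-Curtis similarity of cohort profiles
    to the gold standard, and (when metadata is available) gradient slopes
    per trial.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, metadata, truth = _load_or_simulate(config, outdir)
    filtered, _ = filter_features(table, config.prevalence_min,
                                  config.min_keep, config.filter_mode)

    rng = np.random.default_rng(stage_seed(config.seed, "verify"))
    trials = [("gold", filtered)]
    for frac in subset_fractions:
        for t in range(n_trials_per_fraction):
            n_sub = int(round(frac * filtered.n_samples))
            if n_sub < 10:
                raise ValueError(f"subset of {n_sub} samples is too small")
            samples = list(np.asarray(filtered.sample_ids, dtype=object)[
                rng.permutation(filtered.n_samples)[:n_sub]])
            trials.append((f"subset_{frac:g}_{t + 1}",
                           filtered.select_samples(samples)))

    # common ASV universe: present (count > 0 somewhere) in every trial
    common = set(filtered.asv_ids)
    for _, sub in trials:
        present = np.asarray(sub.asv_ids, dtype=object)[
            (sub.counts > 0).any(axis=0)]
        common &= set(present)
    common = sorted(common)

    partitions, profiles, slopes = [], {}, {}
    names = []
    for name, sub in trials:
        sub = sub.select_asvs(common)
        est = _infer(config, sub)
        net = build_network(est, config.r_threshold, config.p_threshold)
        if net.is_empty:
            raise RuntimeError(f"trial {name!r} produced an empty network")
        cons = consensus_partition(
            net, grid=config.resolution_grid,
            reps_per_resolution=config.reps_per_resolution,
            seed=stage_seed(config.seed, "cluster"))
        partitions.append(cons.partition)
        names.append(name)
        profiles[name] = cohort_profile(sub, cons.partition, dataset_id=name)
        if metadata is not None and metadata.variables:
            abund = cohort_abundance(sub, cons.partition)
            if abund.shape[1] >= 2:
                pair = list(abund.sum(axis=0).sort_values(
                    ascending=False).index[:2])
                lr = cohort_log_ratio(abund, pair[0], pair[1])
                var = (config.env_variables or metadata.variables)[0]
                meta = metadata.aligned_to(sub.sample_ids, strict=False)
                slopes[name] = gradient_correlation(lr, meta[var]).slope

    ari = cross_trial_agreement(partitions)
    ari.index = ari.columns = names

    gold_mat = _aligned_matrix(profiles["gold"])
    bc_to_gold = {}
    for name in names[1:]:
        mat = _aligned_matrix(profiles[name])
        sims = []
        for _, row in mat.iterrows():
            aligned = gold_mat.reindex(columns=mat.columns.union(gold_mat.columns),
                                       fill_value=0.0)
            r = row.reindex(aligned.columns, fill_value=0.0).to_numpy()
            sims.append(max(bray_curtis_similarity(r, g.to_numpy())
                            for _, g in aligned.iterrows()))
        bc_to_gold[name] = float(np.mean(sims))

    report = {"trials": names,
              "ari_matrix": ari.to_dict(),
              "mean_bray_curtis_to_gold": bc_to_gold,
              "gradient_slopes": slopes,
              "n_common_asvs": len(common)}
    (outdir / "verification.json").write_text(json.dumps(report, indent=2))
    return {"report": report, "partitions": dict(zip(names, partitions)),
            "ari": ari}
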