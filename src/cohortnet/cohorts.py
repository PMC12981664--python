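"""Quantitative cohort metrics, compositional stability and cross-trial
agreement.

Cohorts (network clusters of ASVs) are characterized per dataset by four
metrics -- member counts, the fraction of reads mapped to any cohort, cohort
richness per sample, and the inverse-Simpson effective number of cohorts per
sample -- and compared across datasets through Bray-Curtis similarity of
their mean member composition.  Higher-order "cluster-cluster" grouping uses
Ward linkage on Bray-Curtis dissimilarities with the silhouette criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .clustering import Partition
from .io import CountTable, relative_abundance
from .nullmodels import adjusted_rand_index

__all__ = [
    "CohortProfile",
    "CohortGrouping",
    "cohort_sizes",
    "mapped_count_fraction",
    "cohorts_per_sample",
    "effective_cohort_number",
    "cohort_profile",
    "bray_curtis_similarity",
    "cross_cohort_similarity",
    "group_cohorts",
    "cross_trial_agreement",
    "cohort_metrics_frame",
]


def _check_partition_in_table(table: CountTable, partition: Partition) -> None:
    missing = set(partition.labels) - set(table.asv_ids)
    if missing:
        raise ValueError(
            f"partition contains ASVs absent from the table: {sorted(missing)[:5]}")


def cohort_sizes(partition: Partition) -> dict:
    """Number of member ASVs per cohort label."""
    if not partition.labels:
        raise ValueError("empty partition")
    return partition.sizes()


def mapped_count_fraction(table: CountTable, partition: Partition) -> pd.Series:
    """Per sample, the fraction of total reads carried by cohort-member ASVs."""
    _check_partition_in_table(table, partition)
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = np.asarray(table.sample_ids, dtype=object)[totals == 0]
        raise ValueError(f"zero-total sample(s): {bad.tolist()}")
    member_ids = list(partition.labels)
    if not member_ids:
        mapped = np.zeros(table.n_samples)
    else:
        cols = [table.asv_ids.index(a) for a in member_ids]
        mapped = table.counts[:, cols].sum(axis=1)
    return pd.Series(mapped / totals, index=table.sample_ids,
                     name="mapped_fraction")


def _cohort_count_matrix(table: CountTable, partition: Partition) -> pd.DataFrame:
    """Samples x cohorts summed member counts (shared by several metrics)."""
    _check_partition_in_table(table, partition)
    col_index = {a: i for i, a in enumerate(table.asv_ids)}
    labels = sorted(set(partition.labels.values()))
    mat = np.zeros((table.n_samples, len(labels)), dtype=np.int64)
    for k, lab in enumerate(labels):
        cols = [col_index[a] for a, l in partition.labels.items() if l == lab]
        mat[:, k] = table.counts[:, cols].sum(axis=1)
    return pd.DataFrame(mat, index=table.sample_ids, columns=labels)


def cohorts_per_sample(table: CountTable, partition: Partition) -> pd.Series:
    """Cohort richness: cohorts with at least one member read in the sample."""
    cm = _cohort_count_matrix(table, partition)
    return (cm > 0).sum(axis=1).rename("cohort_richness")


def effective_cohort_number(table: CountTable, partition: Partition,
                            include_unassigned: bool = False) -> pd.Series:
    """Inverse-Simpson effective number of cohorts per sample.

    Cohort relative abundances q_c are the cohort-mapped reads renormalized
    (optionally with an extra "unassigned" pseudo-cohort holding all
    non-member reads); ESN = 1 / sum_c q_c^2.  Samples with no mapped reads
    are NaN-coded.
    """
    cm = _cohort_count_matrix(table, partition).to_numpy(dtype=float)
    if include_unassigned:
        totals = table.counts.sum(axis=1).astype(float)
        unassigned = totals - cm.sum(axis=1)
        cm = np.column_stack([cm, unassigned])
    sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = cm / sums[:, None]
        esn = 1.0 / np.nansum(q**2, axis=1)
    esn[sums == 0] = np.nan
    return pd.Series(esn, index=table.sample_ids, name="effective_cohorts")


def cohort_metrics_frame(table: CountTable, partition: Partition) -> pd.DataFrame:
    """Long-format table of the three per-sample cohort metrics."""
    metrics = {
        "mapped_fraction": mapped_count_fraction(table, partition),
        "cohort_richness": cohorts_per_sample(table, partition),
        "effective_cohorts": effective_cohort_number(table, partition),
    }
    rows = []
    for name, series in metrics.items():
        for sample, value in series.items():
            rows.append({"sample_id": sample, "metric": name, "value": value})
    return pd.DataFrame(rows)


@dataclass
class CohortProfile:
    """Mean relative-abundance composition of one cohort in one dataset."""

    dataset_id: str
    cohort: object
    composition: pd.Series  # member ASV -> mean relative abundance, sums to 1

    @property
    def key(self) -> str:
        return f"{self.dataset_id}:{self.cohort}"


def cohort_profile(table: CountTable, partition: Partition,
                   dataset_id: str = "dataset",
                   renormalize: bool = True) -> list:
    """Average member-ASV composition of every cohort.

    Per cohort: the mean (over samples) relative abundance of each member
    ASV, renormalized to sum to 1 within the cohort (``renormalize=False``
    keeps the whole-community scale).
    """
    _check_partition_in_table(table, partition)
    rel = relative_abundance(table)
    profiles = []
    for lab in sorted(set(partition.labels.values())):
        members = [a for a, l in partition.labels.items() if l == lab]
        comp = rel[members].mean(axis=0)
        total = comp.sum()
        if total == 0:
            raise ValueError(f"cohort {lab!r} has no reads in any sample")
        if renormalize:
            comp = comp / total
        profiles.append(CohortProfile(dataset_id, lab, comp))
    return profiles


def bray_curtis_similarity(x, y) -> float:
    """1 - sum|x - y| / sum(x + y) for non-negative composition vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.sum(x + y)
    if denom == 0:
        return 1.0
    return float(1.0 - np.sum(np.abs(x - y)) / denom)


def _aligned_matrix(profiles) -> pd.DataFrame:
    """Profiles as rows aligned on the union of ASV ids (missing = 0)."""
    frame = pd.DataFrame({p.key: p.composition for p in profiles}).T
    return frame.fillna(0.0)


def cross_cohort_similarity(profiles) -> pd.DataFrame:
    """Pairwise Bray-Curtis similarity between cohort profiles.

    Profiles (possibly from different datasets) are aligned on the union of
    their ASV identifiers; absent ASVs count as 0.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 cohort profiles")
    mat = _aligned_matrix(profiles)
    n = mat.shape[0]
    sim = np.ones((n, n))
    arr = mat.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = bray_curtis_similarity(arr[i], arr[j])
    return pd.DataFrame(sim, index=mat.index, columns=mat.index)


@dataclass
class CohortGrouping:
    """Ward dendrogram over cohort profiles with silhouette-optimal groups."""

    linkage: np.ndarray
    profile_keys: list
    group_labels: dict          # profile key -> group id (1..k)
    k: int
    silhouette_by_k: pd.Series  # candidate k -> mean silhouette width

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return str(self.profile_keys[node.id])
            left, right = rec(node.left), rec(node.right)
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return rec(tree) + ";"


def group_cohorts(profiles) -> CohortGrouping:
    """Group cohort profiles into higher-order "cluster-clusters".

    Ward linkage on Bray-Curtis dissimilarities (ward.D convention: the
    Lance-Williams update runs on the dissimilarities as given, achieved by
    feeding their square roots to the squared-input implementation -- merge
    order is identical, heights are a monotone transform).  The group count k
    maximizes the mean silhouette width over k = 2 .. n-1; identical profiles
    degenerate to k = 1 with a warning.
    """
    from sklearn.metrics import silhouette_score

    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to form groups")
    sim = cross_cohort_similarity(profiles)
    dis = 1.0 - sim.to_numpy()
    np.fill_diagonal(dis, 0.0)
    dis = np.clip(dis, 0.0, None)
    keys = list(sim.index)
    n = len(keys)
    condensed = np.sqrt(dis[np.triu_indices(n, k=1)])
    z = hierarchy.linkage(condensed, method="ward")

    if np.allclose(dis, 0.0):
        warnings.warn("all cohort profiles identical; returning a single group")
        return CohortGrouping(z, keys, {k: 1 for k in keys}, 1,
                              pd.Series(dtype=float))

    scores = {}
    labelings = {}
    for k in range(2, n):
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(dis, labels, metric="precomputed"))
        labelings[k] = labels
    if not scores:  # n == 3 with ties, etc.
        labels = hierarchy.fcluster(z, t=2, criterion="maxclust")
        scores, labelings = {2: 0.0}, {2: labels}
    best_k = max(scores, key=lambda k: (scores[k], -k))
    labels = labelings[best_k]
    return CohortGrouping(
        linkage=z, profile_keys=keys,
        group_labels=dict(zip(keys, (int(l) for l in labels))),
        k=best_k, silhouette_by_k=pd.Series(scores).sort_index())


def cross_trial_agreement(partitions) -> pd.DataFrame:
    """Pairwise ARI between trial partitions over their shared ASVs.

    Each partition is restricted to the intersection of all node sets before
    comparison (ASVs missing from any trial are dropped).
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    shared = set(partitions[0].labels)
    for p in partitions[1:]:
        shared &= set(p.labels)
    if not shared:
        raise ValueError("no ASVs shared by all partitions")
    restricted = [p.restricted_to(sorted(shared)) for p in partitions]
    n = len(restricted)
    ari = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ari[i, j] = ari[j, i] = adjusted_rand_index(
                restricted[i], restricted[j])
    names = [f"trial_{i + 1}" for i in range(n)]
    return pd.DataFrame(ari, index=names, columns=names)
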