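"""Community detection on co-occurrence networks.

The central object is the :class:`Partition`, an assignment of every network
node to one cohort label together with its (Newman, weighted) modularity.
Cohorts are obtained with a multi-resolution Leiden consensus
(:class:`ConsensusLeiden` / :func:`consensus_partition`): Leiden is run
repeatedly over a resolution grid, pairwise co-classification frequencies are
collected, pairs co-assigned at least half the time form a consensus graph,
and the procedure iterates on that graph until the co-classification matrix is
binary.  Walktrap (used by the threshold sensitivity sweep) and
Clauset-Newman-Moore greedy agglomeration (used by the rewired null models,
where the dendrogram is cut at a prescribed number of clusters) are also
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd

from .network import CoNetwork

__all__ = [
    "Partition",
    "ConsensusResult",
    "ConsensusLeiden",
    "leiden_partition",
    "consensus_partition",
    "walktrap_partition",
    "greedy_partition",
    "modularity",
    "DEFAULT_RESOLUTION_GRID",
]

#: default multi-resolution grid: 20 values log-spaced over [0.3, 2.0]
DEFAULT_RESOLUTION_GRID = np.geomspace(0.3, 2.0, 20)


@dataclass
class Partition:
    """Node -> cohort assignment with its modularity score.

    Labels are integers, contiguous from 1, ordered by decreasing cohort size.
    """

    labels: dict                    # node id -> int label
    modularity: float
    algorithm: str
    resolution: float | None = None

    @property
    def node_ids(self) -> list:
        return list(self.labels.keys())

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def sizes(self) -> dict:
        out = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return dict(sorted(out.items()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cohort")

    def members(self, label) -> list:
        return [n for n, l in self.labels.items() if l == label]

    def restricted_to(self, node_ids) -> "Partition":
        """Sub-assignment on a node subset (labels kept, Q not recomputed)."""
        sub = {n: self.labels[n] for n in node_ids}
        return Partition(sub, modularity=np.nan, algorithm=self.algorithm,
                         resolution=self.resolution)

    def write_tsv(self, path) -> None:
        self.as_series().rename_axis("asv_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, algorithm: str = "file") -> "Partition":
        s = pd.read_csv(path, sep="\t", index_col=0)["cohort"]
        return cls(labels=s.to_dict(), modularity=np.nan, algorithm=algorithm)


def _canonical_labels(node_ids, raw_labels) -> dict:
    """Relabel to integers 1..k by decreasing cluster size (ties: first seen)."""
    raw = list(raw_labels)
    counts = {}
    for lab in raw:
        counts[lab] = counts.get(lab, 0) + 1
    first_seen = {}
    for i, lab in enumerate(raw):
        first_seen.setdefault(lab, i)
    order = sorted(counts, key=lambda l: (-counts[l], first_seen[l]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return {n: remap[lab] for n, lab in zip(node_ids, raw)}


def modularity(network: CoNetwork, partition: Partition) -> float:
    """Weighted Newman modularity of a partition.

    Q = sum_c ( W_c / W  -  (S_c / 2W)^2 ) with W the total edge weight, W_c
    the intra-community weight and S_c the summed node strength of community
    c.  Every network node must be labelled.
    """
    missing = [n for n in network.node_ids if n not in partition.labels]
    if missing:
        raise ValueError(f"partition missing labels for nodes: {missing[:5]}")
    if network.is_empty:
        raise ValueError("modularity of an empty network is undefined")
    g = network.graph
    w = np.asarray(g.es["weight"], dtype=float)
    total = w.sum()
    labels = np.asarray([partition.labels[n] for n in network.node_ids])
    src = np.asarray([e.source for e in g.es])
    tgt = np.asarray([e.target for e in g.es])
    strengths = np.asarray(g.strength(weights="weight"), dtype=float)

    q = 0.0
    for lab in np.unique(labels):
        members = labels == lab
        intra = w[(members[src]) & (members[tgt])].sum()
        s_c = strengths[members].sum()
        q += intra / total - (s_c / (2.0 * total)) ** 2
    return float(q)


def leiden_partition(network: CoNetwork, resolution: float = 1.0,
                     seed: int = 0) -> Partition:
    """Leiden community detection (modularity objective, edge weights).

    ``resolution`` is the RB resolution parameter gamma; higher values yield
    more, smaller clusters.  The recorded Q is the standard (gamma = 1)
    weighted Newman modularity of the returned partition.
    """
    if network.is_empty:
        raise ValueError("cannot cluster an empty network")
    part = la.find_partition(
        network.graph, la.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=float(resolution),
        seed=int(seed), n_iterations=2)
    labels = _canonical_labels(network.node_ids, part.membership)
    p = Partition(labels, modularity=np.nan, algorithm="leiden",
                  resolution=float(resolution))
    p.modularity = modularity(network, p)
    return p


def walktrap_partition(network: CoNetwork, steps: int = 4) -> Partition:
    """Walktrap agglomerative clustering, cut at the max-modularity level."""
    if network.is_empty:
        raise ValueError("cannot cluster an empty network")
    dendro = network.graph.community_walktrap(weights="weight", steps=steps)
    clustering = dendro.as_clustering()
    labels = _canonical_labels(network.node_ids, clustering.membership)
    p = Partition(labels, modularity=np.nan, algorithm="walktrap")
    p.modularity = modularity(network, p)
    return p


def greedy_partition(network: CoNetwork, k: int | None = None) -> Partition:
    """Clauset-Newman-Moore greedy modularity agglomeration.

    With ``k`` given, the merge dendrogram is cut at exactly ``k`` communities
    (as used for rewired null networks matched to the observed cluster
    number); a disconnected graph cannot be merged below its component count,
    in which case the component count is used.  Without ``k``, the
    max-modularity cut is returned.
    """
    if network.is_empty:
        raise ValueError("cannot cluster an empty network")
    n = network.n_nodes
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    dendro = network.graph.community_fastgreedy(weights="weight")
    if k is None:
        clustering = dendro.as_clustering()
    else:
        n_components = len(network.graph.connected_components())
        clustering = dendro.as_clustering(n=max(k, n_components))
    labels = _canonical_labels(network.node_ids, clustering.membership)
    p = Partition(labels, modularity=np.nan, algorithm="greedy")
    p.modularity = modularity(network, p)
    return p


@dataclass
class ConsensusResult:
    """Outcome of the multi-resolution Leiden consensus."""

    partition: Partition
    resolution_grid: np.ndarray
    mean_resolution: float
    coclassification: pd.DataFrame      # node x node co-assignment frequency
    stability_profile: pd.DataFrame     # per-resolution mean ARI vs consensus
    n_consensus_iter: int = 1

    def summary(self) -> dict:
        return {
            "n_clusters": self.partition.n_clusters,
            "modularity": self.partition.modularity,
            "mean_resolution": self.mean_resolution,
            "resolution_grid": np.asarray(self.resolution_grid).tolist(),
            "stability_profile": self.stability_profile.to_dict("records"),
            "n_consensus_iter": self.n_consensus_iter,
        }


class ConsensusLeiden:
    """Multi-resolution Leiden consensus clustering of a co-occurrence network.

    Fit procedure:

    1. Run Leiden ``reps_per_resolution`` times at every resolution of the
       grid (independent seeds).
    2. Build the node x node co-classification frequency matrix.
    3. Keep pairs co-assigned with frequency >= ``coclass_threshold`` as a
       consensus graph (edge weight = frequency) and re-cluster it with the
       same ensemble; iterate until the co-classification matrix is binary
       (a fully stable partition) or ``max_consensus_iter`` is reached.

    The mean resolution reported for downstream re-clustering (attack
    analysis) is the average of grid resolutions whose first-round partitions
    agree with the consensus at mean ARI >= ``stability_ari_threshold``
    (falling back to the grid mean when none qualify).

    Attributes (after ``fit``): ``labels_``, ``partition_``,
    ``coclassification_``, ``mean_resolution_``, ``stability_profile_``,
    ``result_``.
    """

    def __init__(self, resolution_grid=None, reps_per_resolution: int = 10,
                 coclass_threshold: float = 0.5, max_consensus_iter: int = 5,
                 stability_ari_threshold: float = 0.9, random_state=None):
        self.resolution_grid = resolution_grid
        self.reps_per_resolution = reps_per_resolution
        self.coclass_threshold = coclass_threshold
        self.max_consensus_iter = max_consensus_iter
        self.stability_ari_threshold = stability_ari_threshold
        self.random_state = random_state

    # sklearn-compatible param plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "resolution_grid", "reps_per_resolution", "coclass_threshold",
            "max_consensus_iter", "stability_ari_threshold", "random_state")}

    def set_params(self, **params) -> "ConsensusLeiden":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _ensemble(self, graph: ig.Graph, grid, rng) -> list:
        """(resolution, membership array) for every grid x rep run."""
        runs = []
        for res in grid:
            for _ in range(self.reps_per_resolution):
                seed = int(rng.integers(2**31 - 1))
                part = la.find_partition(
                    graph, la.RBConfigurationVertexPartition,
                    weights="weight", resolution_parameter=float(res),
                    seed=seed, n_iterations=2)
                runs.append((float(res), np.asarray(part.membership)))
        return runs

    @staticmethod
    def _coclassification(memberships, n) -> np.ndarray:
        freq = np.zeros((n, n))
        for m in memberships:
            freq += m[:, None] == m[None, :]
        freq /= len(memberships)
        return freq

    def fit(self, network: CoNetwork):
        from sklearn.metrics import adjusted_rand_score

        if network.is_empty:
            raise ValueError("cannot cluster an empty network")
        grid = (DEFAULT_RESOLUTION_GRID if self.resolution_grid is None
                else np.asarray(self.resolution_grid, dtype=float))
        if grid.size == 0:
            raise ValueError("resolution grid must be non-empty")
        rng = np.random.default_rng(self.random_state)
        node_ids = network.node_ids
        n = len(node_ids)

        first_round = self._ensemble(network.graph, grid, rng)
        freq = self._coclassification([m for _, m in first_round], n)

        final_membership = None
        n_iter = 0
        work_freq = freq
        for n_iter in range(1, self.max_consensus_iter + 1):
            binary = np.all((work_freq >= 1 - 1e-12) | (work_freq <= 1e-12))
            adj = work_freq >= self.coclass_threshold
            np.fill_diagonal(adj, False)
            if binary:
                # stable: clusters are the connected components of the
                # thresholded co-classification graph
                g = ig.Graph.Adjacency(adj.tolist(), mode="undirected")
                final_membership = np.asarray(
                    g.connected_components().membership)
                break
            ii, jj = np.nonzero(np.triu(adj, k=1))
            cons = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
            cons.es["weight"] = work_freq[ii, jj].tolist()
            runs = self._ensemble(cons, grid, rng)
            work_freq = self._coclassification([m for _, m in runs], n)
        if final_membership is None:
            # not fully converged: take a single Leiden pass on the last
            # consensus graph at unit resolution as the majority partition
            adj = work_freq >= self.coclass_threshold
            np.fill_diagonal(adj, False)
            ii, jj = np.nonzero(np.triu(adj, k=1))
            cons = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
            cons.es["weight"] = work_freq[ii, jj].tolist()
            part = la.find_partition(
                cons, la.RBConfigurationVertexPartition, weights="weight",
                resolution_parameter=1.0,
                seed=int(rng.integers(2**31 - 1)), n_iterations=2)
            final_membership = np.asarray(part.membership)

        labels = _canonical_labels(node_ids, final_membership)
        partition = Partition(labels, modularity=np.nan, algorithm="leiden_consensus")
        partition.modularity = modularity(network, partition)

        final_arr = np.asarray([labels[nid] for nid in node_ids])
        profile_rows = []
        for res in grid:
            aris = [adjusted_rand_score(final_arr, m)
                    for r0, m in first_round if r0 == float(res)]
            profile_rows.append({"resolution": float(res),
                                 "mean_ari_vs_consensus": float(np.mean(aris))})
        profile = pd.DataFrame(profile_rows)
        stable = profile["mean_ari_vs_consensus"] >= self.stability_ari_threshold
        mean_resolution = (float(profile.loc[stable, "resolution"].mean())
                           if stable.any() else float(np.mean(grid)))

        self.labels_ = final_arr
        self.partition_ = partition
        self.coclassification_ = pd.DataFrame(freq, index=node_ids,
                                              columns=node_ids)
        self.mean_resolution_ = mean_resolution
        self.stability_profile_ = profile
        self.result_ = ConsensusResult(
            partition=partition, resolution_grid=grid,
            mean_resolution=mean_resolution,
            coclassification=self.coclassification_,
            stability_profile=profile, n_consensus_iter=n_iter)
        return self

    def fit_predict(self, network: CoNetwork) -> np.ndarray:
        return self.fit(network).labels_


def consensus_partition(network: CoNetwork, grid=None,
                        reps_per_resolution: int = 10,
                        coclass_threshold: float = 0.5,
                        max_consensus_iter: int = 5,
                        seed: int = 0) -> ConsensusResult:
    """Functional wrapper over :class:`ConsensusLeiden`; returns its result."""
    est = ConsensusLeiden(
        resolution_grid=grid, reps_per_resolution=reps_per_resolution,
        coclass_threshold=coclass_threshold,
        max_consensus_iter=max_consensus_iter, random_state=seed)
    return est.fit(network).result_
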