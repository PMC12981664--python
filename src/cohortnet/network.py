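"""Positive co-occurrence networks and threshold sensitivity sweeps.

A :class:`CoNetwork` is a weighted undirected graph over ASVs whose edges are
statistically significant positive correlations: a pair is connected iff
``r_ij > r_threshold``, ``p_ij <= p_threshold`` and ``r_ij > 0``.  Nodes left
without any edge are removed.  The module also implements the r-threshold
sensitivity sweep (clustering coefficient, walktrap modularity, cluster count
and mean size across a grid of thresholds).
"""

from __future__ import annotations

import warnings

import igraph as ig
import numpy as np
import pandas as pd

from .cooccurrence import CorrelationEstimate

__all__ = [
    "CoNetwork",
    "build_network",
    "network_from_edge_list",
    "transitivity",
    "threshold_sensitivity",
    "DEFAULT_THRESHOLD_GRID",
]

#: r-threshold grid for the sensitivity sweep: 0.10 to 0.70 in steps of 0.01
DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.10, 0.7001, 0.01), 2)


class CoNetwork:
    """Weighted undirected co-occurrence network over ASVs.

    Thin wrapper around an :mod:`igraph` graph whose vertices carry ASV ids in
    the ``name`` attribute and whose edges carry the correlation in
    ``weight``.  Invariants: simple graph, positive weights, no isolated
    nodes (except the explicit empty network).
    """

    def __init__(self, graph: ig.Graph, r_threshold: float | None = None,
                 p_threshold: float | None = None):
        self.graph = graph
        self.r_threshold = r_threshold
        self.p_threshold = p_threshold

    # -- construction ------------------------------------------------------
    @classmethod
    def from_edges(cls, node_ids, edges, weights, r_threshold=None,
                   p_threshold=None) -> "CoNetwork":
        """Build from node id list and (i, j) index pairs with weights."""
        g = ig.Graph(n=len(node_ids), edges=list(edges))
        g.vs["name"] = list(node_ids)
        g.es["weight"] = [float(w) for w in weights]
        return cls(g, r_threshold, p_threshold)

    # -- properties --------------------------------------------------------
    @property
    def node_ids(self) -> list:
        return list(self.graph.vs["name"]) if self.graph.vcount() else []

    @property
    def n_nodes(self) -> int:
        return self.graph.vcount()

    @property
    def n_edges(self) -> int:
        return self.graph.ecount()

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.graph.es["weight"], dtype=float) \
            if self.graph.ecount() else np.empty(0)

    @property
    def is_empty(self) -> bool:
        return self.graph.ecount() == 0

    def degree_sequence(self) -> dict:
        return dict(zip(self.node_ids, self.graph.degree()))

    def strengths(self) -> dict:
        return dict(zip(self.node_ids,
                        self.graph.strength(weights="weight")))

    def edge_frame(self) -> pd.DataFrame:
        rows = [(self.graph.vs[e.source]["name"], self.graph.vs[e.target]["name"],
                 e["weight"]) for e in self.graph.es]
        return pd.DataFrame(rows, columns=["source", "target", "r"])

    def subgraph(self, node_ids) -> "CoNetwork":
        """Induced subgraph on the given ASV ids (isolated survivors kept)."""
        idx = [self.graph.vs.find(name=n).index for n in node_ids]
        return CoNetwork(self.graph.induced_subgraph(idx),
                         self.r_threshold, self.p_threshold)

    def copy(self) -> "CoNetwork":
        return CoNetwork(self.graph.copy(), self.r_threshold, self.p_threshold)

    def __repr__(self) -> str:
        return f"CoNetwork({self.n_nodes} nodes, {self.n_edges} edges)"

    # -- output ------------------------------------------------------------
    def write_graphml(self, path) -> None:
        self.graph.write_graphml(str(path))

    def write_edgelist_tsv(self, path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for the upper-triangle pairs."""
    n = p.shape[0]
    iu = np.triu_indices(n, k=1)
    raw = p[iu]
    m = raw.size
    order = np.argsort(raw)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum.accumulate(
        (raw[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.zeros_like(p)
    out[iu] = np.clip(adjusted, 0, 1)
    return out + out.T


def build_network(estimate: CorrelationEstimate, r_threshold: float,
                  p_threshold: float = 0.05, positive_only: bool = True,
                  fdr_bh: bool = False) -> CoNetwork:
    """Threshold a correlation estimate into a positive co-occurrence network.

    Edge rule: ``r_ij > r_threshold`` (strict), ``p_ij <= p_threshold`` where
    p-values are present, and ``r_ij > 0`` when ``positive_only``.  Isolated
    nodes are dropped.  A zero-edge result is returned as an explicit empty
    network (0 nodes) for downstream stages to reject.  ``fdr_bh`` applies a
    Benjamini-Hochberg adjustment to the pairwise p-values before the
    ``p_threshold`` cut (off by default: the standard rule is a raw P cut).
    """
    if not -1 <= r_threshold <= 1:
        raise ValueError("r_threshold must be in [-1, 1]")
    if not 0 <= p_threshold <= 1:
        raise ValueError("p_threshold must be in [0, 1]")
    r = estimate.r
    keep = r > r_threshold
    if positive_only:
        keep &= r > 0
    if estimate.p is not None:
        p = _bh_adjust(estimate.p) if fdr_bh else estimate.p
        keep &= p <= p_threshold
    keep = np.triu(keep, k=1)
    ii, jj = np.nonzero(keep)
    net = CoNetwork.from_edges(estimate.asv_ids, list(zip(ii.tolist(), jj.tolist())),
                               r[ii, jj], r_threshold, p_threshold)
    # drop isolated nodes
    isolated = [v.index for v in net.graph.vs if net.graph.degree(v.index) == 0]
    if isolated:
        net.graph.delete_vertices(isolated)
    return net


def network_from_edge_list(path_or_frame, default_weight: float = 1.0) -> CoNetwork:
    """Adapter for externally inferred networks (e.g. conditional-independence
    methods that provide only an unweighted edge list).

    Accepts a TSV path or DataFrame with columns ``source``/``target`` and an
    optional ``r``/``weight`` column; missing weights default to
    ``default_weight`` so the weighted clustering machinery stays usable.
    """
    df = (path_or_frame if isinstance(path_or_frame, pd.DataFrame)
          else pd.read_csv(path_or_frame, sep="\t"))
    wcol = next((c for c in ("r", "weight") if c in df.columns), None)
    nodes = pd.unique(pd.concat([df["source"].astype(str),
                                 df["target"].astype(str)]))
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[str(s)], index[str(t)])
             for s, t in zip(df["source"], df["target"])]
    weights = (df[wcol].astype(float).tolist() if wcol is not None
               else [default_weight] * len(edges))
    return CoNetwork.from_edges(list(nodes), edges, weights)


def transitivity(network: CoNetwork) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples.

    Computed on the unweighted topology.  Graphs with no connected triple
    return 0 by convention (with a warning).
    """
    if network.n_nodes == 0:
        raise ValueError("transitivity of an empty network is undefined")
    degs = np.asarray(network.graph.degree())
    if not np.any(degs >= 2):
        warnings.warn("network has no connected triples; transitivity set to 0")
        return 0.0
    return float(network.graph.transitivity_undirected(mode="zero"))


def threshold_sensitivity(estimate: CorrelationEstimate,
                          grid=None) -> pd.DataFrame:
    """Sweep r-thresholds and characterize each resulting network.

    For each threshold the network is rebuilt and summarized by edge/node
    counts, the global clustering coefficient, walktrap modularity, the mean
    number of members per cluster and the number of clusters.  Thresholds
    yielding an empty network are reported with NaN metrics.
    """
    from .clustering import walktrap_partition  # deferred: avoids module cycle

    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, float)
    rows = []
    for r_thr in grid:
        net = build_network(estimate, float(r_thr))
        row = {"r_threshold": float(r_thr), "n_nodes": net.n_nodes,
               "n_edges": net.n_edges, "clustering_coefficient": np.nan,
               "modularity": np.nan, "mean_cluster_size": np.nan,
               "n_clusters": np.nan}
        if not net.is_empty:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["clustering_coefficient"] = transitivity(net)
            part = walktrap_partition(net)
            sizes = list(part.sizes().values())
            row["modularity"] = part.modularity
            row["mean_cluster_size"] = float(np.mean(sizes))
            row["n_clusters"] = len(sizes)
        rows.append(row)
    return pd.DataFrame(rows)
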