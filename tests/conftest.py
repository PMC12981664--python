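"""Shared fixtures: toy graphs, toy tables, and the planted-cohort runs.

The expensive session fixture ``planted_runs`` executes the full inference
pipeline (clr-Pearson correlations, bootstrap edge significance, r = 0.25
positive network, multi-resolution Leiden consensus) on five independently
seeded default synthetic communities; several recovery/robustness tests share
it.
"""

import numpy as np
import pandas as pd
import pytest

from cohortnet import (CountTable, GeneratorConfig, bootstrap_pvalues,
                       build_network, consensus_partition, generate_community,
                       pearson_clr_correlations)
from cohortnet.clustering import Partition
from cohortnet.network import CoNetwork
from cohortnet.synthetic import BACKGROUND


def make_network(n_nodes, edges, weights=None, node_ids=None):
    """CoNetwork from explicit edges; default weight 1."""
    ids = node_ids or [f"n{i}" for i in range(n_nodes)]
    w = weights if weights is not None else [1.0] * len(edges)
    return CoNetwork.from_edges(ids, edges, w)


def planted_partition(truth, node_ids):
    """Ground-truth Partition over a node subset (background = label 0)."""
    labels = {}
    for n in node_ids:
        m = truth.membership[n]
        labels[n] = 0 if m == BACKGROUND else int(m)
    return Partition(labels, modularity=np.nan, algorithm="planted")


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles: the closed-form Q = 0.5 graph."""
    return make_network(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by a single bridge edge."""
    edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    edges += [(i + 5, j + 5) for i in range(5) for j in range(i + 1, 5)]
    edges += [(4, 5)]
    return make_network(10, edges)


@pytest.fixture
def toy_table():
    """4 samples x 4 ASVs with hand-checkable counts."""
    return CountTable(pd.DataFrame(
        [[10, 5, 3, 2],
         [8, 2, 6, 4],
         [1, 1, 1, 17],
         [5, 5, 5, 5]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c", "d"]))


@pytest.fixture(scope="session")
def planted_runs():
    """Full pipeline runs on 5 seeds of the default planted community."""
    runs = []
    for seed in range(5):
        table, meta, truth = generate_community(GeneratorConfig(seed=seed))
        est = pearson_clr_correlations(table)
        bootstrap_pvalues(table, est, n_boot=200, seed=seed + 100)
        net = build_network(est, 0.25)
        cons = consensus_partition(net, seed=seed + 200)
        runs.append({"seed": seed, "table": table, "meta": meta,
                     "truth": truth, "estimate": est, "network": net,
                     "consensus": cons})
    return runs


# ---------------------------------------------------------------------------
# independent oracles (kept here so every test file shares one implementation)
# ---------------------------------------------------------------------------

def modularity_pair_sum(network, partition) -> float:
    """O(n^2) double-sum oracle: Q = (1/2W) sum_ij (A_ij - s_i s_j / 2W) d_ij."""
    ids = network.node_ids
    n = len(ids)
    index = {v: i for i, v in enumerate(ids)}
    a = np.zeros((n, n))
    for e in network.graph.es:
        i, j = e.source, e.target
        a[i, j] += e["weight"]
        a[j, i] += e["weight"]
    s = a.sum(axis=1)
    two_w = a.sum()
    labels = np.array([partition.labels[v] for v in ids])
    same = labels[:, None] == labels[None, :]
    return float(np.sum((a - np.outer(s, s) / two_w) * same) / two_w)


def ari_pair_counting(labels_a, labels_b) -> float:
    """Brute-force ARI from the four pair categories."""
    from math import comb

    n = len(labels_a)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n11 = sum(1 for i, j in pairs
              if labels_a[i] == labels_a[j] and labels_b[i] == labels_b[j])
    sum_a = sum(comb(c, 2) for c in pd.Series(list(labels_a)).value_counts())
    sum_b = sum(comb(c, 2) for c in pd.Series(list(labels_b)).value_counts())
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def bray_curtis_direct(x, y) -> float:
    """Direct-summation Bray-Curtis similarity oracle."""
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return 1.0 - num / den if den else 1.0
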