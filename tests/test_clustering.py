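"""Leiden / walktrap / greedy partitions, consensus, and modularity."""

import numpy as np
import pytest

from cohortnet import (adjusted_rand_index, consensus_partition,
                       greedy_partition, leiden_partition, modularity,
                       walktrap_partition)
from cohortnet.clustering import ConsensusLeiden, Partition
from cohortnet.network import CoNetwork

from .conftest import make_network, modularity_pair_sum


def random_weighted_network(rng, n=30, p_edge=0.2):
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.append((i, j))
                weights.append(rng.uniform(0.1, 1.0))
    if not edges:
        edges, weights = [(0, 1)], [1.0]
    return make_network(n, edges, weights)


class TestModularity:
    def test_two_disconnected_triangles_give_half(self, two_triangles):
        part = Partition({f"n{i}": 1 if i < 3 else 2 for i in range(6)},
                         np.nan, "manual")
        assert modularity(two_triangles, part) == pytest.approx(0.5)

    def test_single_community_is_zero(self, two_cliques):
        part = Partition({n: 1 for n in two_cliques.node_ids}, np.nan, "manual")
        assert modularity(two_cliques, part) == pytest.approx(0.0)

    def test_agrees_with_pair_sum_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            net = random_weighted_network(rng, n=int(rng.integers(10, 50)))
            labels = {n: int(rng.integers(1, 5)) for n in net.node_ids}
            part = Partition(labels, np.nan, "random")
            assert modularity(net, part) == pytest.approx(
                modularity_pair_sum(net, part), abs=1e-10)

    def test_missing_label_errors(self, two_triangles):
        part = Partition({"n0": 1}, np.nan, "manual")
        with pytest.raises(ValueError, match="missing"):
            modularity(two_triangles, part)


class TestLeiden:
    def test_two_triangles_found_with_closed_form_q(self, two_triangles):
        part = leiden_partition(two_triangles, resolution=1.0, seed=1)
        assert part.n_clusters == 2
        assert part.modularity == pytest.approx(0.5)

    def test_complete_graph_is_one_cluster(self):
        net = make_network(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        assert leiden_partition(net, 1.0, seed=2).n_clusters == 1

    def test_deterministic_under_fixed_seed(self, two_cliques):
        p1 = leiden_partition(two_cliques, 1.0, seed=3)
        p2 = leiden_partition(two_cliques, 1.0, seed=3)
        assert adjusted_rand_index(p1, p2) == 1.0
        assert p1.labels == p2.labels

    def test_empty_network_rejected(self):
        empty = CoNetwork.from_edges([], [], [])
        with pytest.raises(ValueError):
            leiden_partition(empty)


class TestWalktrapAndGreedy:
    def test_walktrap_splits_disconnected_triangles(self, two_triangles):
        part = walktrap_partition(two_triangles)
        assert part.n_clusters == 2
        assert part.modularity == pytest.approx(
            modularity(two_triangles, part))

    def test_walktrap_star_is_single_cluster(self):
        star = make_network(5, [(0, i) for i in range(1, 5)])
        assert walktrap_partition(star).n_clusters == 1

    def test_greedy_dendrogram_cuts(self, two_cliques):
        n = two_cliques.n_nodes
        assert greedy_partition(two_cliques, k=n).n_clusters == n
        p1 = greedy_partition(two_cliques, k=1)
        assert p1.n_clusters == 1
        assert p1.modularity == pytest.approx(0.0)
        p2 = greedy_partition(two_cliques, k=2)
        assert p2.n_clusters == 2
        first = {f"n{i}" for i in range(5)}
        side = {n for n in p2.labels if p2.labels[n] == p2.labels["n0"]}
        assert side == first

    def test_greedy_k_out_of_range(self, two_cliques):
        with pytest.raises(ValueError):
            greedy_partition(two_cliques, k=11)

    def test_leiden_q_not_worse_than_walktrap_on_planted_graphs(self):
        rng = np.random.default_rng(7)
        wins = 0
        for trial in range(10):
            # 3-block planted graph: dense blocks, sparse background
            blocks = [range(0, 12), range(12, 24), range(24, 36)]
            edges, weights = [], []
            for i in range(36):
                for j in range(i + 1, 36):
                    same = any(i in b and j in b for b in blocks)
                    if rng.random() < (0.5 if same else 0.03):
                        edges.append((i, j))
                        weights.append(1.0)
            net = make_network(36, edges, weights)
            ql = leiden_partition(net, 1.0, seed=trial).modularity
            qw = walktrap_partition(net).modularity
            wins += ql >= qw - 1e-12
        assert wins >= 9


class TestConsensus:
    def test_disconnected_triangles_force_binary_coclassification(
            self, two_triangles):
        res = consensus_partition(two_triangles, grid=[0.5, 1.0, 1.5],
                                  reps_per_resolution=3, seed=0)
        assert res.partition.n_clusters == 2
        cc = res.coclassification.to_numpy()
        assert np.all((cc == 0) | (cc == 1))
        assert res.partition.modularity == pytest.approx(0.5)

    def test_mean_resolution_within_grid(self, two_cliques):
        res = consensus_partition(two_cliques, grid=[0.4, 0.8, 1.2],
                                  reps_per_resolution=3, seed=1)
        assert 0.4 <= res.mean_resolution <= 1.2

    def test_invariant_to_node_ordering(self, two_cliques):
        perm = np.random.default_rng(2).permutation(two_cliques.n_nodes)
        ids = np.asarray(two_cliques.node_ids, dtype=object)[perm]
        shuffled = two_cliques.subgraph(list(ids))
        r1 = consensus_partition(two_cliques, grid=[1.0], reps_per_resolution=3,
                                 seed=3)
        r2 = consensus_partition(shuffled, grid=[1.0], reps_per_resolution=3,
                                 seed=3)
        assert adjusted_rand_index(r1.partition, r2.partition) == 1.0

    def test_estimator_api_params_round_trip(self):
        est = ConsensusLeiden(reps_per_resolution=4, random_state=1)
        params = est.get_params()
        assert params["reps_per_resolution"] == 4
        est.set_params(reps_per_resolution=6)
        assert est.reps_per_resolution == 6
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_empty_grid_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            consensus_partition(two_triangles, grid=[])
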