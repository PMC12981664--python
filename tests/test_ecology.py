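"""Cohort abundances, gradients, preferences, PERMANOVA, sample modularity."""

import numpy as np
import pandas as pd
import pytest

from cohortnet import (CountTable, SampleMetadata, bray_curtis_distance_matrix,
                       cohort_abundance, cohort_log_ratio,
                       environmental_preference, gradient_correlation,
                       leiden_partition, modularity, modularity_gradient_fit,
                       permanova, sample_modularity)
from cohortnet.clustering import Partition

from .conftest import make_network


def part(labels):
    return Partition(labels, np.nan, "manual")


@pytest.fixture
def abund_fixture():
    table = CountTable(pd.DataFrame(
        [[10, 10, 5, 5, 3],
         [2, 0, 4, 4, 1],
         [1, 1, 0, 0, 0]],
        index=["s1", "s2", "s3"], columns=list("abcde")))
    partition = part({"a": 1, "b": 1, "c": 2, "d": 2})
    return table, partition


class TestCohortAbundance:
    def test_block_sums_by_hand(self, abund_fixture):
        table, partition = abund_fixture
        abund = cohort_abundance(table, partition)
        assert abund[1].tolist() == [20, 2, 2]
        assert abund[2].tolist() == [10, 8, 0]

    def test_reads_conserved_with_unassigned_column(self, abund_fixture):
        table, partition = abund_fixture
        abund = cohort_abundance(table, partition, include_unassigned=True)
        assert (abund.sum(axis=1).to_numpy()
                == table.counts.sum(axis=1)).all()

    def test_single_cohort_of_everything_equals_sample_totals(self, abund_fixture):
        table, _ = abund_fixture
        p = part({a: 1 for a in table.asv_ids})
        abund = cohort_abundance(table, p)
        assert (abund[1].to_numpy() == table.counts.sum(axis=1)).all()


class TestLogRatio:
    def test_closed_forms_and_depth_invariance(self):
        abund = pd.DataFrame({1: [4, int(np.e * 1000), 7],
                              2: [4, 1000, 7]}, index=["s1", "s2", "s3"])
        lr = cohort_log_ratio(abund, 1, 2, pseudocount=0)
        assert lr["s1"] == pytest.approx(0.0)
        assert lr["s3"] == pytest.approx(0.0)
        assert lr["s2"] == pytest.approx(1.0, abs=1e-3)
        scaled = cohort_log_ratio(abund * 10, 1, 2, pseudocount=0)
        assert np.allclose(lr, scaled)

    def test_unknown_cohort_rejected(self):
        abund = pd.DataFrame({1: [1, 2]}, index=["s1", "s2"])
        with pytest.raises(KeyError):
            cohort_log_ratio(abund, 1, 99)


class TestGradientCorrelation:
    def test_exact_line_recovered(self):
        x = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        fit = gradient_correlation(2 * x, x)
        assert fit.r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_permuted_response_decorrelates(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(300)]
        x = pd.Series(np.linspace(0, 1, 300), index=idx)
        y = pd.Series(rng.permutation(x.to_numpy()), index=idx)
        assert abs(gradient_correlation(y, x).r) < 0.15

    def test_zero_variance_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            gradient_correlation(y, x)


class TestEnvironmentalPreference:
    def test_weighted_means_and_z_columns(self):
        idx = [f"s{i}" for i in range(4)]
        abund = pd.DataFrame({1: [1, 0, 0, 0], 2: [0, 0, 0, 3],
                              3: [1, 1, 1, 1]}, index=idx)
        meta = SampleMetadata(pd.DataFrame({"temp": [0.0, 1.0, 2.0, 3.0]},
                                           index=idx))
        pref = environmental_preference(abund, meta)
        # cohort present in exactly one sample -> that sample's value
        assert pref.weighted_means.loc[1, "temp"] == 0.0
        assert pref.weighted_means.loc[2, "temp"] == 3.0
        assert pref.weighted_means.loc[3, "temp"] == 1.5
        z = pref.z["temp"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)
        # mirror-image weights -> opposite-sign z-scores
        assert np.sign(z[1]) == -np.sign(z[2])


class TestPermanova:
    def test_r2_decomposition_sums_to_one(self):
        rng = np.random.default_rng(1)
        from cohortnet import generate_null_community
        table = generate_null_community(25, 30, 2000, seed=2)
        d = bray_curtis_distance_matrix(table)
        pred = pd.DataFrame({"x": rng.normal(size=25),
                             "y": rng.normal(size=25)},
                            index=table.sample_ids)
        res = permanova(d, pred, n_perm=99, seed=3)
        assert res.terms["R2"].sum() == pytest.approx(1.0, abs=1e-10)
        assert res.terms.loc["residual", "df"] == 25 - 3

    def test_disjoint_groups_are_fully_separable(self):
        # two groups with disjoint compositions
        counts = np.zeros((12, 6), dtype=int)
        rng = np.random.default_rng(4)
        counts[:6, :3] = rng.integers(50, 100, (6, 3))
        counts[6:, 3:] = rng.integers(50, 100, (6, 3))
        table = CountTable.from_arrays(counts, [f"s{i}" for i in range(12)],
                                       list("abcdef"))
        d = bray_curtis_distance_matrix(table)
        pred = pd.DataFrame({"group": [0] * 6 + [1] * 6},
                            index=table.sample_ids)
        res = permanova(d, pred, n_perm=199, seed=5)
        assert res.terms.loc["group", "R2"] > 0.5
        assert res.terms.loc["group", "p"] == pytest.approx(1 / 200)

    def test_pseudo_f_matches_reference_implementation(self):
        """Binary-predictor pseudo-F equals the one-way PERMANOVA of skbio."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        from cohortnet import generate_null_community
        table = generate_null_community(20, 25, 2000, seed=6)
        d = bray_curtis_distance_matrix(table)
        groups = [0] * 10 + [1] * 10
        pred = pd.DataFrame({"g": groups}, index=table.sample_ids)
        ours = permanova(d, pred, n_perm=49, seed=7)
        theirs = skbio_permanova(DistanceMatrix(d.to_numpy(),
                                                ids=table.sample_ids),
                                 grouping=[str(g) for g in groups],
                                 permutations=49)
        assert ours.terms.loc["g", "F"] == pytest.approx(
            theirs["test statistic"], rel=1e-10)

    def test_rank_deficient_design_lists_alias(self):
        idx = [f"s{i}" for i in range(6)]
        d = pd.DataFrame(np.ones((6, 6)) - np.eye(6), index=idx, columns=idx)
        pred = pd.DataFrame({"x": [1, 2, 3, 4, 5, 6],
                             "x2": [2, 4, 6, 8, 10, 12]}, index=idx)
        with pytest.raises(ValueError, match="x2"):
            permanova(d, pred, n_perm=9)


class TestSampleModularity:
    def test_full_sample_equals_network_modularity(self, two_triangles):
        partition = leiden_partition(two_triangles, seed=0)
        counts = np.ones((2, 6), dtype=int)
        table = CountTable.from_arrays(counts, ["s1", "s2"],
                                       two_triangles.node_ids)
        sq = sample_modularity(two_triangles, partition, table)
        assert sq["s1"] == pytest.approx(modularity(two_triangles, partition))

    def test_single_cohort_sample_has_zero_modularity(self, two_triangles):
        partition = leiden_partition(two_triangles, seed=0)
        counts = np.array([[1, 1, 1, 0, 0, 0],
                           [1, 1, 1, 1, 1, 1]])
        table = CountTable.from_arrays(counts, ["only_first", "all"],
                                       two_triangles.node_ids)
        sq = sample_modularity(two_triangles, partition, table)
        assert sq["only_first"] == pytest.approx(0.0)

    def test_edgeless_subgraph_is_missing_coded(self, two_triangles):
        partition = leiden_partition(two_triangles, seed=0)
        counts = np.array([[1, 0, 0, 1, 0, 0],
                           [1, 1, 1, 1, 1, 1]])
        table = CountTable.from_arrays(counts, ["sparse", "all"],
                                       two_triangles.node_ids)
        sq = sample_modularity(two_triangles, partition, table)
        assert np.isnan(sq["sparse"])


class TestCubicFit:
    def test_exact_cubic_recovered(self):
        x = pd.Series(np.linspace(-2, 2, 30), index=range(30))
        z = (x - x.mean()) / x.std(ddof=0)
        y = 1.0 + 2.0 * z - 0.5 * z**2 + 0.25 * z**3
        fit = modularity_gradient_fit(y, x)
        assert np.allclose(fit.coefficients, [1.0, 2.0, -0.5, 0.25], atol=1e-8)
        assert np.allclose(fit.predict(x), y, atol=1e-8)

    def test_constant_response_kills_higher_orders(self):
        x = pd.Series(np.linspace(0, 1, 20), index=range(20))
        y = pd.Series(np.full(20, 3.0), index=range(20))
        fit = modularity_gradient_fit(y, x)
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-10)
        assert fit.coefficients[0] == pytest.approx(3.0)

    def test_too_few_points_rejected(self):
        x = pd.Series([1.0, 2, 3, 4], index=range(4))
        with pytest.raises(ValueError):
            modularity_gradient_fit(x, x)
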