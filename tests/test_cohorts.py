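"""Cohort metrics, compositional profiles, Bray-Curtis and grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortnet import (CountTable, bray_curtis_similarity, cohort_profile,
                       cohort_sizes, cohorts_per_sample,
                       cross_cohort_similarity, cross_trial_agreement,
                       effective_cohort_number, group_cohorts,
                       mapped_count_fraction)
from cohortnet.clustering import Partition
from cohortnet.cohorts import CohortProfile

from .conftest import bray_curtis_direct


def part(labels):
    return Partition(labels, np.nan, "manual")


@pytest.fixture
def three_cohort_fixture():
    """6 ASVs in 3 cohorts over 3 samples with hand-checkable counts."""
    table = CountTable(pd.DataFrame(
        # cohort 1: a,b   cohort 2: c,d   cohort 3: e   unassigned: f
        [[10, 10, 5, 5, 0, 10],
         [0, 0, 4, 4, 2, 0],
         [3, 0, 0, 0, 0, 17]],
        index=["s1", "s2", "s3"], columns=list("abcdef")))
    partition = part({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3})
    return table, partition


class TestMetrics:
    def test_cohort_sizes_and_conservation(self):
        p = part({"a": 1, "b": 1, "c": 2})
        assert cohort_sizes(p) == {1: 2, 2: 1}
        singletons = part({f"x{i}": i for i in range(5)})
        assert sum(cohort_sizes(singletons).values()) == 5

    def test_mapped_fraction_hand_values(self, three_cohort_fixture):
        table, partition = three_cohort_fixture
        mf = mapped_count_fraction(table, partition)
        assert mf["s1"] == pytest.approx(30 / 40)
        assert mf["s2"] == pytest.approx(1.0)
        assert mf["s3"] == pytest.approx(3 / 20)

    def test_empty_partition_maps_nothing(self, three_cohort_fixture):
        table, _ = three_cohort_fixture
        assert (mapped_count_fraction(table, part({})) == 0).all()

    def test_cohort_richness_hand_enumeration(self, three_cohort_fixture):
        table, partition = three_cohort_fixture
        rich = cohorts_per_sample(table, partition)
        assert rich.tolist() == [2, 2, 1]  # s1: {1,2}; s2: {2,3}; s3: {1}

    def test_effective_number_closed_forms(self):
        table = CountTable(pd.DataFrame(
            [[10, 0, 0, 0],     # one cohort only -> 1
             [5, 5, 0, 0],      # 50/50 over two cohorts -> 2
             [8, 4, 4, 0]],     # (0.5, 0.25, 0.25) -> 1/0.375
            index=["s1", "s2", "s3"], columns=list("abcd")))
        p = part({"a": 1, "b": 2, "c": 3})
        esn = effective_cohort_number(table, p)
        assert esn["s1"] == pytest.approx(1.0)
        assert esn["s2"] == pytest.approx(2.0)
        assert esn["s3"] == pytest.approx(1 / 0.375)

    def test_effective_number_bounded_by_richness(self, three_cohort_fixture):
        table, partition = three_cohort_fixture
        esn = effective_cohort_number(table, partition)
        rich = cohorts_per_sample(table, partition)
        assert (esn <= rich + 1e-12).all()
        assert (esn >= 1.0).all()


class TestProfiles:
    def test_single_sample_profile_is_renormalized_row(self):
        table = CountTable(pd.DataFrame([[6, 2, 2], [6, 2, 2]],
                                        index=["s1", "s2"],
                                        columns=list("abc")))
        profiles = cohort_profile(table, part({"a": 1, "b": 1}))
        comp = profiles[0].composition
        assert comp["a"] == pytest.approx(0.75)
        assert comp["b"] == pytest.approx(0.25)

    def test_toy_two_cohort_profiles_by_hand(self, three_cohort_fixture):
        table, partition = three_cohort_fixture
        profiles = {p.cohort: p for p in cohort_profile(table, partition)}
        # cohort 2 (c, d): per-sample relative abundances are equal for c and
        # d in every sample, so the renormalized profile is (0.5, 0.5)
        assert profiles[2].composition["c"] == pytest.approx(0.5)
        assert np.isclose(profiles[1].composition.sum(), 1.0)

    def test_empty_cohort_errors(self):
        table = CountTable(pd.DataFrame([[1, 0], [2, 0]], index=["s1", "s2"],
                                        columns=["a", "dead"]))
        with pytest.raises(ValueError, match="no reads"):
            cohort_profile(table, part({"a": 1, "dead": 2}))


class TestBrayCurtis:
    def test_closed_forms(self):
        assert bray_curtis_similarity([1, 2, 3], [1, 2, 3]) == 1.0
        assert bray_curtis_similarity([1, 0], [0, 1]) == 0.0
        x = np.array([1, 1, 0]) / 2
        y = np.array([0, 1, 1]) / 2
        assert bray_curtis_similarity(x, y) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=8),
           st.integers(0, 2**31 - 1))
    def test_range_and_direct_summation_oracle(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 100, len(x))
        sim = bray_curtis_similarity(x, y)
        assert -1e-12 <= sim <= 1 + 1e-12
        assert sim == pytest.approx(bray_curtis_direct(x, y), abs=1e-12)

    def test_cross_cohort_similarity_aligns_on_asv_union(self):
        p1 = CohortProfile("d1", 1, pd.Series({"a": 0.5, "b": 0.5}))
        p2 = CohortProfile("d2", 1, pd.Series({"a": 0.5, "b": 0.5}))
        p3 = CohortProfile("d2", 2, pd.Series({"x": 1.0}))
        sim = cross_cohort_similarity([p1, p2, p3])
        assert sim.loc["d1:1", "d2:1"] == 1.0
        assert sim.loc["d1:1", "d2:2"] == 0.0
        assert np.allclose(sim, sim.T)


class TestGrouping:
    def _blob_profiles(self, rng, center, n, tag):
        out = []
        for i in range(n):
            comp = np.abs(center + rng.normal(0, 0.01, len(center)))
            comp /= comp.sum()
            out.append(CohortProfile(tag, i + 1, pd.Series(
                comp, index=[f"asv{j}" for j in range(len(center))])))
        return out

    def test_two_blobs_found_as_two_groups(self):
        rng = np.random.default_rng(0)
        a = self._blob_profiles(rng, np.array([1.0, 1.0, 0.0, 0.0]), 4, "A")
        b = self._blob_profiles(rng, np.array([0.0, 0.0, 1.0, 1.0]), 4, "B")
        grouping = group_cohorts(a + b)
        assert grouping.k == 2
        groups_a = {grouping.group_labels[p.key] for p in a}
        groups_b = {grouping.group_labels[p.key] for p in b}
        assert len(groups_a) == len(groups_b) == 1
        assert groups_a != groups_b
        assert grouping.to_newick().endswith(";")

    def test_group_labels_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        a = self._blob_profiles(rng, np.array([1.0, 0.0]), 3, "A")
        b = self._blob_profiles(rng, np.array([0.0, 1.0]), 3, "B")
        g1 = group_cohorts(a + b)
        g2 = group_cohorts(b + a)
        same1 = [g1.group_labels[p.key] == g1.group_labels[a[0].key]
                 for p in a + b]
        same2 = [g2.group_labels[p.key] == g2.group_labels[a[0].key]
                 for p in a + b]
        assert same1 == same2

    def test_identical_profiles_degenerate_to_one_group(self):
        p = [CohortProfile("d", i, pd.Series({"a": 0.5, "b": 0.5}))
             for i in range(4)]
        with pytest.warns(UserWarning, match="identical"):
            grouping = group_cohorts(p)
        assert grouping.k == 1


class TestCrossTrialAgreement:
    def test_self_agreement_and_symmetry(self):
        p1 = part({"a": 1, "b": 1, "c": 2, "d": 2})
        p2 = part({"a": 1, "b": 2, "c": 2, "d": 2, "extra": 3})
        ari = cross_trial_agreement([p1, p2, p1])
        assert ari.iloc[0, 2] == 1.0  # identical trials
        assert np.allclose(ari, ari.T)
        assert np.allclose(np.diag(ari), 1.0)

    def test_disjoint_partitions_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            cross_trial_agreement([part({"a": 1, "b": 1}), part({"c": 1, "d": 1})])
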