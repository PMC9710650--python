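from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from proteoflow import exploratory as ex
from proteoflow.design_tree import GroupAssignment, build_design, groups_at_level
from proteoflow.errors import InsufficientDataError, ProteoflowError
from proteoflow.io_maxquant import load_intensity_table
from proteoflow.thresholding import Category, ThresholdPolicy, categorize

POLICY = ThresholdPolicy()
NA = np.nan


def two_groups(samples_a, samples_b):
    return GroupAssignment(level=0, groups={"A": samples_a, "B": samples_b})


class TestDetectionCounts:
    def test_histogram_bins_and_totals(self):
        table = make_table(
            [[1, 2, 3], [1, NA, 3], [NA, NA, NA], [1, NA, NA]],
            samples=["A_1", "A_2", "A_3"],
        )
        groups = GroupAssignment(0, {"A": ["A_1", "A_2", "A_3"]})
        res = ex.detection_counts(groups, table)
        hist = res.histograms["A"]
        assert hist.to_dict() == {1: 1, 2: 1, 3: 1}
        assert res.totals["A"] == 3  # never-detected protein excluded

    def test_matches_generator_bookkeeping(self, default_fixture):
        path, spec, truth = default_fixture
        table = load_intensity_table(path, "raw")
        design = build_design(spec.sample_names)
        groups = groups_at_level(design, 0)
        res = ex.detection_counts(groups, table)
        detected = ~truth.missing_mask.loc[truth.unflagged]
        for group, samples in groups.groups.items():
            counts = detected[samples].sum(axis=1)
            assert res.totals[group] == int((counts > 0).sum())
            expected_hist = counts[counts > 0].value_counts().to_dict()
            observed = {k: v for k, v in res.histograms[group].items() if v > 0}
            assert observed == expected_hist


class TestDetectedPerSample:
    def test_counts_and_averages(self):
        table = make_table([[1, 2], [3, NA], [NA, NA]], samples=["A_1", "A_2"])
        res = ex.detected_per_sample(GroupAssignment(0, {"A": ["A_1", "A_2"]}), table)
        assert res.per_sample.set_index("sample")["detected"].to_dict() == {
            "A_1": 2, "A_2": 1
        }
        assert res.group_totals["A"] == 2
        assert res.group_averages["A"] == pytest.approx(1.5)


class TestVenn:
    def test_identical_samples_only_full_intersection(self):
        table = make_table([[1, 1], [2, 2]], samples=["s1", "s2"])
        res = ex.venn_within_group(["s1", "s2"], table)
        sizes = {tuple(sorted(k)): len(v) for k, v in res.regions.items()}
        assert sizes == {("s1",): 0, ("s2",): 0, ("s1", "s2"): 2}

    def test_regions_match_brute_force_set_algebra(self):
        rng = np.random.default_rng(0)
        matrix = rng.normal(size=(30, 4))
        matrix[rng.random(matrix.shape) < 0.4] = NA
        table = make_table(matrix)
        res = ex.venn_within_group(list(table.sample_names), table)
        sets = {s: set(table.values.index[table.values[s].notna()])
                for s in table.sample_names}
        union = set().union(*sets.values())
        # disjoint and complete
        all_regions = list(res.regions.values())
        assert sum(len(r) for r in all_regions) == len(union)
        assert set().union(*all_regions) == union
        # each region verified element-wise
        for members, proteins in res.regions.items():
            for p in union:
                inside = {s for s in sets if p in sets[s]}
                assert (p in proteins) == (inside == set(members))

    def test_style_switches_and_cardinality_limit(self):
        matrix = np.ones((3, 7))
        table = make_table(matrix)
        names = table.sample_names
        assert ex.venn_within_group(names[:3], table).style == "classic"
        assert ex.venn_within_group(names[:5], table).style == "bar"
        with pytest.raises(ProteoflowError, match="at most 6"):
            ex.venn_within_group(names, table)

    def test_between_groups_uses_threshold(self):
        # protein 1: 3/3 in A, 1/3 in B -> only in A's set
        table = make_table(
            [[1, 1, 1, 1, NA, NA], [1, 1, 1, 1, 1, 1]],
            samples=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
        )
        groups = two_groups(["A_1", "A_2", "A_3"], ["B_1", "B_2", "B_3"])
        res = ex.venn_between_groups(groups, table, POLICY)
        assert res.regions[frozenset({"A"})] == {"p1"}
        assert res.regions[frozenset({"A", "B"})] == {"p2"}


class TestPCA:
    def test_duplicated_samples_project_identically(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=20)
        matrix = np.column_stack([col, col, rng.normal(size=20)])
        table = make_table(matrix, samples=["A_1", "A_2", "B_1"])
        groups = two_groups(["A_1", "A_2"], ["B_1"])
        res = ex.pca_overview(groups, table)
        a1 = res.coordinates.loc["A_1", ["PC1", "PC2"]].astype(float)
        a2 = res.coordinates.loc["A_2", ["PC1", "PC2"]].astype(float)
        np.testing.assert_allclose(a1, a2, atol=1e-9)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_complete_case_rule_excludes_missing_proteins(self):
        matrix = np.array([[1.0, 2, 3], [4, NA, 6], [7, 8, 9], [1, 3, 2]])
        table = make_table(matrix, samples=["A_1", "A_2", "B_1"])
        groups = two_groups(["A_1", "A_2"], ["B_1"])
        res = ex.pca_overview(groups, table)
        assert res.n_proteins == 3

    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(2)
        base = rng.normal(25, 2, size=100)
        a = base[:, None] + rng.normal(0, 0.2, (100, 3))
        b = base[:, None] + 3.0 + rng.normal(0, 0.2, (100, 3))
        table = make_table(
            np.hstack([a, b]),
            samples=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
        )
        groups = two_groups(["A_1", "A_2", "A_3"], ["B_1", "B_2", "B_3"])
        res = ex.pca_overview(groups, table)
        pc1 = res.coordinates["PC1"]
        assert (pc1[:3] < pc1[3:].min()).all() or (pc1[:3] > pc1[3:].max()).all()

    def test_too_few_complete_proteins(self):
        table = make_table([[1.0, NA], [NA, 2.0], [3.0, 4.0]])
        with pytest.raises(InsufficientDataError):
            ex.pca_overview(GroupAssignment(0, {"g": ["s1", "s2"]}), table)


class TestIntensityHistogram:
    def test_counts_sum_to_observed_values(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(25, 2, size=(50, 3))
        matrix[rng.random(matrix.shape) < 0.2] = NA
        table = make_table(matrix)
        res = ex.intensity_histogram(table.sample_names, table, bins=10)
        for s in table.sample_names:
            assert res.counts[s].sum() == table.values[s].notna().sum()

    def test_against_independent_binning(self):
        matrix = np.array([[20.0, 21], [22, 23], [24, 25]])
        table = make_table(matrix)
        res = ex.intensity_histogram(table.sample_names, table, bins=5)
        for j, s in enumerate(table.sample_names):
            expected, _ = np.histogram(matrix[:, j], bins=res.bin_edges)
            np.testing.assert_array_equal(res.counts[s], expected)
        assert res.group_mean_intensity == pytest.approx(matrix.mean())


class TestRelativeSD:
    def test_constant_protein_is_zero_percent(self):
        table = make_table([[5.0, 5, 5]])
        res = ex.relative_sd(table.sample_names, table, POLICY)
        assert res.frame_["rsd_percent"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_on_linear_scale(self):
        # log2 values give linear {2, 4, 8}
        table = make_table([[1.0, 2, 3]])
        res = ex.relative_sd(table.sample_names, table, POLICY)
        linear = np.array([2.0, 4, 8])
        expected = linear.std(ddof=1) / linear.mean() * 100
        assert res.frame_["rsd_percent"].iloc[0] == pytest.approx(expected)

    def test_below_threshold_protein_excluded(self):
        table = make_table([[1.0, 2, 3], [1.0, NA, NA]])
        res = ex.relative_sd(table.sample_names, table, POLICY)
        assert res.frame_["protein"].tolist() == ["p1"]


class TestScatterReplicates:
    def test_self_correlation_and_unique_lists(self):
        table = make_table([[1.0, 1.0], [2.0, 2.1], [3.0, NA]])
        res = ex.scatter_replicates(table.sample_names, table)
        pair = res.pairs[0]
        assert pair.unique_x == ["p3"]
        assert pair.unique_y == []
        assert len(pair.pairs) == 2
        assert res.correlation.loc["s1", "s1"] == 1.0

    def test_r2_matches_kernel(self, default_fixture):
        path, spec, truth = default_fixture
        table = load_intensity_table(path, "raw")
        samples = spec.sample_names[:3]
        res = ex.scatter_replicates(samples, table)
        from proteoflow.stats_inference import pearson_r2
        for pair in res.pairs:
            both = table.values[[pair.name_x, pair.name_y]].dropna()
            assert pair.r_squared == pytest.approx(
                pearson_r2(both.iloc[:, 0], both.iloc[:, 1])
            )


class TestExperimentComparison:
    def test_unique_classification_consistent_with_categorize(self, default_fixture):
        path, spec, truth = default_fixture
        table = load_intensity_table(path, "raw")
        groups = groups_at_level(build_design(spec.sample_names), 0)
        res = ex.experiment_comparison(groups, table, POLICY)
        (ga, gb) = list(groups.groups)
        pair = res.pairs[0]
        n_a, n_b = len(groups.groups[ga]), len(groups.groups[gb])
        for protein in table.values.index:
            det_a = int(table.values.loc[protein, groups.groups[ga]].notna().sum())
            det_b = int(table.values.loc[protein, groups.groups[gb]].notna().sum())
            label = categorize(det_a, n_a, det_b, n_b, POLICY)
            assert (protein in set(pair.pairs["protein"])) == (
                label is Category.COMPARABLE
            )
            assert (protein in pair.unique_x) == (label is Category.UNIQUE_IN_A)
            assert (protein in pair.unique_y) == (label is Category.UNIQUE_IN_B)


class TestRank:
    def test_endpoints_and_three_protein_percentiles(self):
        table = make_table([[30.0], [20.0], [25.0]], samples=["s1"])
        res = ex.rank_plot(["s1"], table)
        frame = res.frame_
        assert frame.iloc[0]["protein"] == "p1"  # highest intensity
        assert frame["rank_percent"].tolist() == [0.0, 50.0, 100.0]

    def test_single_protein_ranks_zero(self):
        table = make_table([[30.0]], samples=["s1"])
        assert ex.rank_plot(["s1"], table).frame_["rank_percent"].tolist() == [0.0]

    def test_pathway_membership_and_median(self):
        table = make_table([[30.0], [29.0], [20.0], [10.0]], samples=["s1"])
        res = ex.rank_plot(["s1"], table, {"mypath": {"P2", "p4"}})
        frame = res.frame_.set_index("protein")
        assert frame.loc["p2", "pathway"] == "mypath"  # case-insensitive
        assert frame.loc["p4", "pathway"] == "mypath"
        stats = res.pathway_stats.iloc[0]
        assert stats["detected"] == 2
        expected_median = np.median([frame.loc["p2", "rank_percent"],
                                     frame.loc["p4", "rank_percent"]])
        assert stats["median_rank_percent"] == pytest.approx(expected_median)


class TestPathwayAnalysis:
    def test_below_threshold_pair_has_no_p_value(self):
        table = make_table(
            [[1.0, 1.1, 0.9, 2.0, NA, NA]],
            samples=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
        )
        groups = two_groups(["A_1", "A_2", "A_3"], ["B_1", "B_2", "B_3"])
        res = ex.pathway_analysis(groups, table, {"path": {"p1"}}, POLICY)
        assert len(res.p_values) == 0
        assert len(res.intensities) == 6

    def test_p_matches_t_test_kernel(self):
        table = make_table(
            [[1.0, 1.1, 0.9, 2.0, 2.1, 1.9]],
            samples=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
        )
        groups = two_groups(["A_1", "A_2", "A_3"], ["B_1", "B_2", "B_3"])
        res = ex.pathway_analysis(groups, table, {"path": {"p1"}}, POLICY)
        from proteoflow.stats_inference import independent_t_test
        _, expected, _ = independent_t_test([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        assert res.p_values["p_value"].iloc[0] == pytest.approx(expected)


class TestGOAnalysis:
    def test_disjoint_term_counts_zero_p_one(self):
        table = make_table([[1.0, 2.0]], samples=["A_1", "A_2"])
        groups = GroupAssignment(0, {"A": ["A_1", "A_2"]})
        res = ex.go_analysis(groups, table, {"term": {"NOTMEASURED"}})
        row = res.frame_.iloc[0]
        assert row["detected_in_term"] == 0
        assert row["p_value"] == pytest.approx(1.0)
        assert row["term_size"] == 1

    def test_planted_enrichment_matches_enumeration(self):
        # 20 proteins; 5 in term; group detects exactly the 5 in-term + 3 others
        matrix = np.full((20, 2), np.nan)
        detected_rows = list(range(5)) + [10, 11, 12]
        for i in detected_rows:
            matrix[i] = [25.0, 25.0]
        table = make_table(matrix, samples=["A_1", "A_2"])
        groups = GroupAssignment(0, {"A": ["A_1", "A_2"]})
        term = {f"p{i+1}" for i in range(5)}
        res = ex.go_analysis(groups, table, {"term": term})
        from test_stats_inference import brute_force_fisher_upper
        expected = brute_force_fisher_upper(5, 0, 3, 12)
        assert res.frame_.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)
        assert expected < 0.01


class TestVolcano:
    def run_volcano(self, path, spec, **kwargs):
        table = load_intensity_table(path, "raw")
        groups = groups_at_level(build_design(spec.sample_names), 0)
        (ga, gb) = list(groups.groups)
        return table, ex.volcano(
            ga, groups.groups[ga], gb, groups.groups[gb], table, POLICY, **kwargs
        )

    def test_categories_partition_protein_set(self, default_fixture):
        path, spec, truth = default_fixture
        table, res = self.run_volcano(path, spec)
        listed = (
            list(res.stats["protein"])
            + list(res.unique_a["protein"])
            + list(res.unique_b["protein"])
            + res.excluded
        )
        assert sorted(listed) == sorted(table.values.index)

    def test_unique_proteins_not_in_t_test_set(self, default_fixture):
        path, spec, truth = default_fixture
        _, res = self.run_volcano(path, spec)
        overlap = set(res.stats["protein"]) & (
            set(res.unique_a["protein"]) | set(res.unique_b["protein"])
        )
        assert not overlap

    def test_annotations_capped_at_top_ten(self, clean_fixture):
        path, spec, truth = clean_fixture
        _, res = self.run_volcano(path, spec)
        assert len(res.annotations) <= 10
        # annotated proteins are the smallest adjusted p-values
        top = set(res.stats.nsmallest(10, "adjusted_p_value")["protein"])
        assert set(res.annotations) <= top

    def test_null_comparison_controls_false_positives(self):
        rng = np.random.default_rng(9)
        base = rng.normal(25, 2, 300)
        matrix = base[:, None] + rng.normal(0, 0.3, (300, 8))
        samples = [f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)]
        table = make_table(matrix, samples=samples)
        res = ex.volcano("A", samples[:4], "B", samples[4:], table, POLICY)
        assert (res.stats["adjusted_p_value"] < 0.05).mean() < 0.02
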