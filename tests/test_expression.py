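"""Normalization, QC, flag filtering and fold-change calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panicleheat import (
    TREATMENT_TIME_POINTS,
    ExpressionDataset,
    FoldChangeTable,
    baseline_to_median,
    default_design,
    differential_probes,
    flag_filter,
    fold_changes,
    heat_responsive,
    intersect_all_timepoints,
    map_probes_to_genes,
    quantile_normalize,
    replicate_correlation,
)
from panicleheat.simulate import default_expression_config, generate_expression_dataset


def make_dataset(values: np.ndarray, flags=None, probe_gene=None) -> ExpressionDataset:
    design = default_design()
    n = values.shape[0]
    probes = [f"P{i}" for i in range(n)]
    values = pd.DataFrame(values, index=probes, columns=design.index)
    if flags is None:
        flags = pd.DataFrame("P", index=probes, columns=design.index)
    else:
        flags = pd.DataFrame(flags, index=probes, columns=design.index)
    if probe_gene is None:
        probe_gene = pd.Series([f"G{i}" for i in range(n)], index=probes)
    return ExpressionDataset(values=values, flags=flags, design=design, probe_gene=probe_gene)


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_hand_computed_rank_means(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        expected = pd.DataFrame({"a": [2.5, 3.5, 4.5], "b": [2.5, 3.5, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_ties_within_a_column_get_their_mean_rank_mean(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        # rank means: (1.5, 2.5, 5.5); tied 1s in column a share (1.5+2.5)/2
        assert out["a"].tolist() == [2.0, 2.0, 5.5]
        assert out["b"].tolist() == [1.5, 2.5, 5.5]

    @given(
        st.integers(2, 30), st.integers(2, 6), st.integers(0, 2**31 - 1)
    )
    @settings(max_examples=50, deadline=None)
    def test_columns_share_one_distribution_afterwards(self, nrow, ncol, seed):
        # continuous entries: the defining property is exact only without
        # within-column ties (the tie rule averages rank-means)
        arr = np.random.default_rng(seed).normal(size=(nrow, ncol))
        out = quantile_normalize(pd.DataFrame(arr)).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_single_column_warns_and_passes_through(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)


class TestBaselineToMedian:
    def test_constant_row_becomes_zero(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0]])
        assert (baseline_to_median(m) == 0).all().all()

    def test_hand_example(self):
        out = baseline_to_median(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert out.iloc[0].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 12)))
        once = baseline_to_median(m)
        pd.testing.assert_frame_equal(baseline_to_median(once), once)


class TestReplicateCorrelation:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        values = np.column_stack([base, base, -base] + [rng.normal(size=50) for _ in range(9)])
        ds = make_dataset(values)
        report = replicate_correlation(ds.values, ds.design)
        assert report.correlations.iloc[0, 1] == pytest.approx(1.0)
        assert report.correlations.iloc[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_column_reported_as_failure(self):
        values = np.random.default_rng(2).normal(size=(30, 12))
        values[:, 0] = 7.0
        ds = make_dataset(values)
        report = replicate_correlation(ds.values, ds.design)
        row = report.replicate_pairs.iloc[0]
        assert np.isnan(row["r"]) and not row["passed"]

    def test_synthetic_replicates_correlate_and_merge_first(self):
        cfg = default_expression_config(seed=3, n_probes=5000, noise_sd=0.05)
        dataset, _ = generate_expression_dataset(cfg)
        report = replicate_correlation(dataset.values, dataset.design)
        assert (report.replicate_pairs["r"] > 0.99).all()
        assert report.all_passed
        # the six lowest merges in the complete-linkage tree join replicate pairs
        samples = list(dataset.values.columns)
        first_merges = report.linkage[:6, :2].astype(int)
        merged = {
            tuple(sorted((samples[i], samples[j]))) for i, j in first_merges
        }
        expected = {
            tuple(sorted(pair))
            for pair in zip(report.replicate_pairs["sample_a"], report.replicate_pairs["sample_b"])
        }
        assert merged == expected


class TestFlagFilter:
    def test_present_call_boundary(self):
        flags = np.array(
            [
                ["P"] * 6 + ["A"] * 6,   # kept: exactly 6 P
                ["P"] * 5 + ["A"] * 7,   # removed: 5 P
                ["M"] * 12,              # removed: no P
                ["P"] * 12,              # kept
            ]
        )
        ds = make_dataset(np.zeros((4, 12)), flags=flags)
        kept = flag_filter(ds)
        assert list(kept) == ["P0", "P3"]

    def test_threshold_rescales_for_other_sample_counts(self):
        design = default_design().iloc[:10]
        values = pd.DataFrame(np.zeros((2, 10)), columns=design.index)
        flags = pd.DataFrame(
            [["P"] * 5 + ["A"] * 5, ["P"] * 4 + ["A"] * 6], columns=design.index
        )
        ds = ExpressionDataset(values, flags, design, pd.Series(dtype=object))
        with pytest.warns(UserWarning, match="rescaled to 5"):
            kept = flag_filter(ds)
        assert list(kept) == [0]


class TestFoldChanges:
    def test_arithmetic(self):
        values = np.zeros((3, 12))
        values[0] = [3.0] * 2 + [4.585] * 10      # ~3-fold up everywhere
        values[1] = [5.0] * 2 + [3.0] * 10        # 4-fold down
        values[2] = [2.0] * 12                    # null
        ds = make_dataset(values)
        fct = fold_changes(ds)
        assert fct.log2fc.loc["P0"].to_numpy() == pytest.approx([1.585] * 5)
        assert fct.log2fc.loc["P1"].to_numpy() == pytest.approx([-2.0] * 5)
        assert fct.log2fc.loc["P2"].to_numpy() == pytest.approx([0.0] * 5)

    def test_column_order_fixed(self):
        ds = make_dataset(np.zeros((2, 12)))
        assert list(fold_changes(ds).log2fc.columns) == list(TREATMENT_TIME_POINTS)


def fct_from_rows(rows: dict) -> FoldChangeTable:
    return FoldChangeTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=TREATMENT_TIME_POINTS)
    )


class TestDifferentialCalls:
    def test_strict_threshold(self):
        fct = fct_from_rows(
            {
                "four_fold_up": [2.0, 0, 0, 0, 0],
                "exactly_three_fold": [math.log2(3), 0, 0, 0, 0],
                "three_fold_down": [-1.7, 0, 0, 0, 0],
            }
        )
        calls = differential_probes(fct, fold=3)
        assert calls.up["20min"] == {"four_fold_up"}
        assert calls.down["20min"] == {"three_fold_down"}
        assert "exactly_three_fold" not in calls.differential("20min")

    def test_fold_threshold_must_exceed_one(self):
        fct = fct_from_rows({"p": [0, 0, 0, 0, 0]})
        with pytest.raises(ValueError):
            differential_probes(fct, fold=1.0)

    def test_intersection_and_hr_membership(self):
        fct = fct_from_rows(
            {
                "all5": [2, 2, 2, 2, 2],
                "four_of_five": [2, 2, 2, 2, 0],
                "two_mixed": [2, 0, 0, 0, -2],   # up early, down late
                "one_only": [2, 0, 0, 0, 0],
            }
        )
        probe_gene = pd.Series({p: f"g_{p}" for p in fct.probes})
        calls = differential_probes(fct)
        inter, genes = intersect_all_timepoints(calls, probe_gene)
        assert inter == {"all5"} and genes == {"g_all5"}
        hr = heat_responsive(calls, probe_gene)
        assert hr.probes == {"all5", "four_of_five", "two_mixed"}
        assert hr.genes == {"g_all5", "g_four_of_five", "g_two_mixed"}

    def test_monotonicity_in_fold_and_min_timepoints(self):
        rng = np.random.default_rng(5)
        rows = {f"p{i}": rng.normal(0, 2, 5) for i in range(200)}
        fct = fct_from_rows(rows)
        weak = differential_probes(fct, fold=2)
        strong = differential_probes(fct, fold=4)
        for tp in TREATMENT_TIME_POINTS:
            assert strong.up[tp] <= weak.up[tp]
            assert strong.down[tp] <= weak.down[tp]
        calls = differential_probes(fct, fold=3)
        sets = [heat_responsive(calls, min_timepoints=k).probes for k in range(1, 6)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger
        inter, _ = intersect_all_timepoints(calls)
        assert inter <= sets[-1]

    def test_min_timepoints_bounded(self):
        fct = fct_from_rows({"p": [0, 0, 0, 0, 0]})
        with pytest.raises(ValueError):
            heat_responsive(differential_probes(fct), min_timepoints=6)


class TestProbeGeneMapping:
    def test_many_to_one_collapse_and_unannotated_warning(self):
        probe_gene = pd.Series({"P1": "G", "P2": "G", "P3": np.nan})
        with pytest.warns(UserWarning, match="1 probe"):
            genes = map_probes_to_genes({"P1", "P2", "P3"}, probe_gene)
        assert genes == {"G"}

    def test_any_probe_rule(self):
        probe_gene = pd.Series({"P1": "G", "P2": "G"})
        assert map_probes_to_genes({"P1"}, probe_gene) == {"G"}

    def test_gene_count_never_exceeds_probe_count(self):
        cfg = default_expression_config(seed=8, n_probes=500, n_planted_per_cluster=30)
        dataset, _ = generate_expression_dataset(cfg)
        calls = differential_probes(fold_changes(dataset))
        hr = heat_responsive(calls, dataset.probe_gene)
        assert len(hr.genes) <= len(hr.probes)
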