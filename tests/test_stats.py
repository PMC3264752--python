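"""Threshold calibration, decile binning and the nonparametric test battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import melanotrack as mt
from oracles import dunn_z, kruskal_h, kruskal_permutation_p, mann_whitney_exact, spearman_r


def events_table(speeds, mmfi=None, cell_id="cell", size=None):
    speeds = list(speeds)
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "track_id": 0,
            "frame": range(len(speeds)),
            "speed_um_s": speeds,
            "mmfi_ch1": mmfi if mmfi is not None else np.arange(len(speeds), dtype=float),
            "size_um2": size if size is not None else 0.1,
        }
    )


# ---------------------------------------------------------------------------
# threshold calibration and classification
# ---------------------------------------------------------------------------

def test_threshold_is_maximum_calibration_speed():
    threshold = mt.calibrate_static_threshold(events_table([0.01, 0.02, 0.05]))
    assert threshold.value == pytest.approx(0.05)
    assert threshold.source == "fixed_calibration"
    assert threshold.n_calibration_events == 3

    single = mt.calibrate_static_threshold(events_table([0.013]))
    assert single.value == pytest.approx(0.013)


def test_default_threshold_when_no_calibration_supplied():
    threshold = mt.calibrate_static_threshold(None)
    assert threshold.value == pytest.approx(0.05)
    assert threshold.source == "default"


def test_empty_calibration_set_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        mt.calibrate_static_threshold(events_table([]))


def test_classification_is_inclusive_at_threshold():
    threshold = mt.StaticThreshold(value=0.05, source="default")
    static = mt.classify_static(events_table([0.05, 0.050001, 0.01]), threshold)
    assert static.tolist() == [True, False, True]


def test_calibration_sample_classifies_itself_fully_static():
    rng = np.random.default_rng(0)
    sample = events_table(rng.rayleigh(0.01, 500))
    threshold = mt.calibrate_static_threshold(sample)
    assert mt.classify_static(sample, threshold).all()


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_ten_distinct_values_fill_one_bin_each():
    events = events_table(np.zeros(10), mmfi=[5, 3, 9, 1, 7, 0, 8, 2, 6, 4])
    binning = mt.bin_by_variable(events, "mmfi_ch1")
    ordered = binning.events.sort_values("mmfi_ch1")
    assert ordered["bin"].tolist() == list(range(10))


def test_bin_occupancy_matches_rank_formula_for_103_events():
    events = events_table(np.zeros(103), mmfi=np.random.default_rng(1).normal(size=103))
    binning = mt.bin_by_variable(events, "mmfi_ch1")
    sizes = binning.events["bin"].value_counts().sort_index()
    expected = np.bincount((np.arange(103) * 10) // 103)  # rank-formula oracle
    assert sizes.tolist() == expected.tolist()
    assert sizes.sum() == 103
    assert sizes.max() - sizes.min() <= 1


def test_bins_are_ordered_by_variable():
    events = events_table(np.zeros(57), mmfi=np.random.default_rng(2).uniform(size=57))
    binning = mt.bin_by_variable(events, "mmfi_ch1")
    maxima = binning.events.groupby("bin")["mmfi_ch1"].max()
    minima = binning.events.groupby("bin")["mmfi_ch1"].min()
    assert (maxima.values[:-1] <= minima.values[1:]).all()


def test_binning_is_independent_per_cell():
    a = events_table(np.zeros(20), mmfi=np.arange(20.0), cell_id="a")
    b = events_table(np.zeros(20), mmfi=np.arange(20.0) + 1000, cell_id="b")
    binning = mt.bin_by_variable(pd.concat([a, b], ignore_index=True), "mmfi_ch1")
    per_cell = binning.events.groupby(["cell_id", "bin"]).size()
    assert (per_cell == 2).all()


def test_undersized_cell_is_named_in_error():
    events = events_table(np.zeros(5), cell_id="tiny")
    with pytest.raises(ValueError, match="tiny"):
        mt.bin_by_variable(events, "mmfi_ch1")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(10, 400), st.integers(0, 2**31 - 1), st.booleans())
def test_binning_conserves_events_and_balances_sizes(n, seed, with_ties):
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 5, n).astype(float) if with_ties else rng.normal(size=n)
    binning = mt.bin_by_variable(events_table(np.zeros(n), mmfi=values), "mmfi_ch1")
    sizes = binning.events["bin"].value_counts()
    assert sizes.sum() == n
    assert set(binning.events["bin"]) == set(range(10))
    assert sizes.max() - sizes.min() <= 1


# ---------------------------------------------------------------------------
# summaries and aggregation
# ---------------------------------------------------------------------------

def test_bin_summary_medians_and_percent_static():
    events = events_table([0.0, 0.0, 0.1, 0.3], mmfi=[1.0, 2.0, 3.0, 4.0])
    binning = mt.bin_by_variable(events, "mmfi_ch1", n_bins=2)
    binning.events["bin"] = 0  # collapse into a single bin for the oracle case
    summary = mt.summarize_bins(binning, mt.StaticThreshold(0.05, "default"))
    row = summary.iloc[0]
    assert row["percent_static"] == pytest.approx(50.0)
    assert row["median_speed_total"] == pytest.approx(0.05)
    assert row["median_speed_motile"] == pytest.approx(0.2)
    assert row["n_total"] == 4 and row["n_motile"] == 2


def test_all_static_bin_flags_motile_median_undefined():
    events = events_table([0.0, 0.01, 0.02, 0.01], mmfi=[1.0, 2.0, 3.0, 4.0])
    binning = mt.bin_by_variable(events, "mmfi_ch1", n_bins=2)
    summary = mt.summarize_bins(binning, mt.StaticThreshold(0.05, "default"))
    assert (summary["percent_static"] == 100.0).all()
    assert summary["median_speed_motile"].isna().all()


def test_aggregate_mean_and_sem_of_cell_medians():
    summaries = pd.DataFrame(
        {
            "cell_id": ["a", "b"],
            "bin": [0, 0],
            "n_total": [10, 10],
            "n_motile": [5, 5],
            "percent_static": [50.0, 50.0],
            "median_speed_total": [0.03, 0.05],
            "median_speed_motile": [0.1, 0.1],
        }
    )
    agg = mt.aggregate_cells(summaries)
    assert agg["mean_median_speed_total"].iloc[0] == pytest.approx(0.04)
    assert agg["sem_median_speed_total"].iloc[0] == pytest.approx(0.01)
    assert agg["sem_median_speed_motile"].iloc[0] == pytest.approx(0.0)


def test_single_cell_aggregate_flags_sem_undefined():
    summaries = pd.DataFrame(
        {
            "cell_id": ["a"],
            "bin": [0],
            "n_total": [10],
            "n_motile": [5],
            "percent_static": [50.0],
            "median_speed_total": [0.03],
            "median_speed_motile": [0.1],
        }
    )
    agg = mt.aggregate_cells(summaries)
    assert agg["mean_median_speed_total"].iloc[0] == pytest.approx(0.03)
    assert np.isnan(agg["sem_median_speed_total"].iloc[0])


# ---------------------------------------------------------------------------
# hypothesis tests vs oracles
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_h_and_no_significant_pairs():
    report = mt.kruskal_wallis_dunn([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
    assert report.statistic == 0.0
    assert report.p_value == 1.0
    assert (report.posthoc_p_adjusted == 1.0).all()


def test_kruskal_h_matches_rank_sum_oracle():
    groups = [[1.2, 3.4, 2.2, 5.0], [2.1, 4.4, 4.5, 6.1], [0.5, 1.1, 2.0, 1.4]]
    report = mt.kruskal_wallis_dunn(groups)
    assert report.statistic == pytest.approx(kruskal_h(groups), abs=1e-10)


def test_kruskal_p_close_to_exact_permutation_enumeration():
    """Chi-square p agrees with the exact permutation null at tiny n."""
    groups = [[1.0, 2.0, 6.0], [3.0, 5.0, 8.0], [4.0, 7.0, 9.0]]
    report = mt.kruskal_wallis_dunn(groups)
    exact = kruskal_permutation_p(groups, report.statistic)
    assert report.p_value == pytest.approx(exact, abs=0.06)


def test_dunn_z_matrix_matches_hand_formula():
    groups = [[1.0, 2.0, 6.0], [3.0, 5.0, 8.0], [4.0, 7.0, 9.0]]
    report = mt.kruskal_wallis_dunn(groups)
    np.testing.assert_allclose(report.posthoc_z, dunn_z(groups), atol=1e-10)
    assert report.adjustment == "bonferroni"
    assert (report.posthoc_p_adjusted <= 1.0).all()


def test_dunn_handles_ties_in_pooled_sample():
    groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 4.0]]
    report = mt.kruskal_wallis_dunn(groups)
    np.testing.assert_allclose(report.posthoc_z, dunn_z(groups), atol=1e-10)


def test_mann_whitney_matches_exact_enumeration():
    report = mt.mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    u, p = mann_whitney_exact([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert report.statistic == pytest.approx(u)  # U = 0
    assert report.p_value == pytest.approx(p)  # exact two-sided p = 0.1
    assert report.statistic == 0.0 and report.p_value == pytest.approx(0.1)


def test_mann_whitney_symmetry():
    a, b = [1.0, 4.0, 2.5, 7.0], [3.0, 5.0, 6.0]
    fwd = mt.mann_whitney(a, b)
    rev = mt.mann_whitney(b, a)
    assert fwd.p_value == pytest.approx(rev.p_value)
    assert rev.statistic == pytest.approx(len(a) * len(b) - fwd.statistic)


def test_mann_whitney_identical_samples_p_is_one():
    report = mt.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert report.p_value == pytest.approx(1.0, abs=1e-6)


def test_spearman_perfect_monotone_decrease():
    report = mt.spearman_with_ci([1.0, 2.0, 3.0, 4.0], [9.0, 7.0, 5.0, 1.0])
    assert report.r == pytest.approx(-1.0)


def test_spearman_with_ties_matches_midrank_oracle():
    x = [1.0, 2.0, 2.0, 3.0, 4.0]
    y = [5.0, 3.0, 4.0, 2.0, 1.0]
    report = mt.spearman_with_ci(x, y)
    assert report.r == pytest.approx(spearman_r(x, y), abs=1e-12)
    lo, hi = report.r_ci95
    assert lo <= report.r <= hi


def test_spearman_rejects_tiny_samples_and_flags_zero_variance():
    with pytest.raises(ValueError):
        mt.spearman_with_ci([1.0, 2.0], [1.0, 2.0])
    report = mt.spearman_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert report.undefined


def test_spearman_recovers_negative_coupling_from_generator():
    config = mt.SimulationConfig(
        n_particles=150, n_frames=21, field_size=(40.0, 40.0), coupling_strength=1.0, seed=31
    )
    truth = mt.simulate_ground_truth(config)
    events = mt.ground_truth_events(truth, config.frame_interval, rng=31)
    report = mt.spearman_with_ci(events["mmfi_ch1"], events["speed_um_s"])
    assert len(events) == 3000
    assert report.r < 0
    assert report.p_value < 1e-3


def test_size_vs_mmfi_correlation():
    events = events_table(np.zeros(20), mmfi=np.arange(20.0), size=np.exp(-np.arange(20.0)))
    report = mt.size_vs_mmfi(events)
    assert report.r == pytest.approx(-1.0)

    constant = events_table(np.zeros(20), mmfi=np.arange(20.0), size=0.3)
    assert mt.size_vs_mmfi(constant).undefined


def test_size_uncorrelated_with_mmfi_under_null_generator():
    config = mt.SimulationConfig(
        n_particles=150, n_frames=11, field_size=(40.0, 40.0), coupling_strength=0.0, seed=41
    )
    truth = mt.simulate_ground_truth(config)
    events = mt.ground_truth_events(truth, config.frame_interval, rng=41)
    report = mt.size_vs_mmfi(events)
    assert abs(report.r) < 3.0 / np.sqrt(config.n_particles)


def test_distribution_summary_percentiles():
    summary = mt.distribution_summary(events_table(np.arange(1.0, 101.0)))
    assert summary["median"] == pytest.approx(50.5)
    assert summary["p5"] == pytest.approx(5.95)  # 1 + 0.05*99
    assert summary["p95"] == pytest.approx(95.05)

    single = mt.distribution_summary(events_table([0.7]))
    assert all(single[k] == pytest.approx(0.7) for k in ("p5", "p25", "median", "p75", "p95"))


def test_distribution_summary_matches_hand_interpolation():
    rng = np.random.default_rng(3)
    speeds = np.sort(rng.uniform(0, 1, 20))
    summary = mt.distribution_summary(events_table(speeds))
    # linear interpolation oracle at p25: index (n-1)*0.25 = 4.75
    expected_p25 = speeds[4] + 0.75 * (speeds[5] - speeds[4])
    assert summary["p25"] == pytest.approx(expected_p25, abs=1e-12)
    expected_p95 = speeds[18] + 0.05 * (speeds[19] - speeds[18])
    assert summary["p95"] == pytest.approx(expected_p95, abs=1e-12)
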