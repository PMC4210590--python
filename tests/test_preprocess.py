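"""Spot summarization, absent flooring, the dual retention rule and quantile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tucr.preprocess import (
    ExpressionMatrix,
    FilterParams,
    detection_filter,
    floor_absent,
    log2_transform,
    preprocess_pipeline,
    quantile_normalize,
    summarize_spots,
)
from tucr.synthetic import SyntheticConfig, generate_dataset

from conftest import random_matrix


def spot_frame(replicates, flags=None, probe=("uc.1", "plus"), sample="s1"):
    flags = flags if flags is not None else [0] * len(replicates)
    return pd.DataFrame(
        {
            "ucr_id": probe[0],
            "strand": probe[1],
            "sample_id": sample,
            "replicate": range(1, len(replicates) + 1),
            "intensity": replicates,
            "flag": flags,
        }
    )


class TestSummarizeSpots:
    @pytest.mark.parametrize(
        "replicates, flags, expected",
        [
            ([10, 10, 10, 10], None, 10.0),  # identical replicates
            ([10, 12, 14, 16], None, 13.0),  # arithmetic mean
            ([10, 12, 14, 16], [0, 0, 0, -50], 12.0),  # flagged spot excluded
        ],
    )
    def test_replicate_averaging(self, replicates, flags, expected):
        matrix = summarize_spots(spot_frame(replicates, flags))
        assert matrix.values.loc["uc.1-plus", "s1"] == expected
        assert matrix.scale == "linear"

    def test_fully_flagged_cell_is_zeroed_and_marked_absent(self, caplog):
        spots = pd.concat(
            [
                spot_frame([10, 12], flags=[-50, -50], sample="s1"),
                spot_frame([20, 30], sample="s2"),
            ]
        )
        with caplog.at_level("WARNING"):
            matrix = summarize_spots(spots)
        assert matrix.values.loc["uc.1-plus", "s1"] == 0.0
        assert not matrix.detection.loc["uc.1-plus", "s1"]
        assert matrix.detection.loc["uc.1-plus", "s2"]
        assert "no unflagged spots" in caplog.text

    def test_invariant_to_replicate_order(self):
        base = spot_frame([3.0, 7.0, 11.0, 19.0])
        shuffled = base.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = summarize_spots(base)
        b = summarize_spots(shuffled)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_duplicate_spot_rows_rejected(self):
        dup = pd.concat([spot_frame([1.0]), spot_frame([2.0])])
        with pytest.raises(ValueError, match="duplicate"):
            summarize_spots(dup)


class TestFloorAbsent:
    def matrix(self, values):
        return ExpressionMatrix(pd.DataFrame(values, index=["p1"], columns=["s1", "s2", "s3"]))

    def test_zero_floor_leaves_matrix_unchanged(self):
        m = self.matrix([[1.0, 50.0, 100.0]])
        out = floor_absent(m, 0.0)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert out.detection.to_numpy().all()

    def test_values_below_floor_are_raised_and_marked_absent(self):
        out = floor_absent(self.matrix([[1.0, 50.0, 100.0]]), 32.0)
        assert out.values.loc["p1"].tolist() == [32.0, 50.0, 100.0]
        assert out.detection.loc["p1"].tolist() == [False, True, True]

    def test_auto_floor_equals_independent_fifth_percentile(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 100, size=(10, 10))
        m = ExpressionMatrix(pd.DataFrame(vals))
        out = floor_absent(m, "auto")
        # independent oracle: linear-interpolated percentile of the sorted pool
        flat = np.sort(vals.ravel())
        rank = 0.05 * (flat.size - 1)
        lo, frac = int(np.floor(rank)), rank - np.floor(rank)
        oracle = flat[lo] * (1 - frac) + flat[lo + 1] * frac
        floored_min = out.values.to_numpy().min()
        assert floored_min == pytest.approx(oracle)
        assert (~out.detection.to_numpy()).sum() == (vals < oracle).sum()

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            floor_absent(self.matrix([[1.0, 2.0, 3.0]]), -1.0)


def brute_force_filter(values, mask, params):
    """Independent reimplementation of both retention rules, probe by probe."""
    retained = []
    for pid in values.index:
        row = values.loc[pid].to_numpy()
        present = mask.loc[pid].to_numpy().mean()
        med = float(np.median(row))
        # v/med > fc or med/v > fc, rearranged so zero medians/values work
        changed = sum(1 for v in row if v > params.fold_change * med or v < med / params.fold_change)
        if present >= params.present_frac and changed / row.size >= params.fc_frac:
            retained.append(pid)
    return retained


class TestDetectionFilter:
    def test_everything_at_the_floor_retains_nothing(self):
        m = ExpressionMatrix(pd.DataFrame(np.full((5, 10), 32.0)))
        m = floor_absent(m, 32.0)
        m.detection.iloc[:, :] = False  # all absent calls
        retained, report = detection_filter(m, FilterParams())
        assert retained == []
        assert not report["retained"].any()

    def test_20_percent_boundaries_are_inclusive(self):
        # present in exactly 2/10 samples, 3/10 beyond 1.5x of the median
        row = [100.0, 300.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 4.0]
        values = pd.DataFrame([row], index=["p"], columns=[f"s{i}" for i in range(10)])
        mask = values >= 32.0
        assert mask.to_numpy().sum() == 2
        m = ExpressionMatrix(values, "linear", mask)
        retained, report = detection_filter(m, FilterParams())
        assert report.loc[0, "present_frac"] == 0.2
        assert report.loc[0, "fc_frac"] == 0.3
        assert retained == ["p"]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_dual_rule_oracle(self, seed):
        m = floor_absent(random_matrix(5, 10, seed), "auto")
        params = FilterParams(fold_change=1.5)
        retained, _ = detection_filter(m, params)
        assert retained == brute_force_filter(m.values, m.detection, params)

    def test_monotone_in_both_thresholds(self):
        m = floor_absent(random_matrix(40, 12, 99), "auto")
        base, _ = detection_filter(m, FilterParams(present_frac=0.2, fc_frac=0.2, fold_change=1.5))
        for params in (
            FilterParams(present_frac=0.5, fc_frac=0.2, fold_change=1.5),
            FilterParams(present_frac=0.2, fc_frac=0.5, fold_change=1.5),
            FilterParams(present_frac=0.2, fc_frac=0.2, fold_change=3.0),
        ):
            tighter, _ = detection_filter(m, params)
            assert set(tighter) <= set(base)


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        col = [5.0, 1.0, 3.0]
        m = ExpressionMatrix(pd.DataFrame({"a": col, "b": col}))
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_hand_computed_rank_wise_means(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}))
        out = quantile_normalize(m)
        assert out.values["a"].tolist() == [2.5, 3.5, 4.5]
        assert out.values["b"].tolist() == [2.5, 3.5, 4.5]

    def test_ties_get_the_mean_reference_value(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [3.0, 4.0, 5.0]}))
        out = quantile_normalize(m)
        # reference = mean of sorted columns = [2, 2.5, 3.5]; the tie in column
        # a spans ranks 1-2 so both copies get (2 + 2.5) / 2
        assert out.values["a"].tolist() == [2.25, 2.25, 3.5]
        assert out.values["b"].tolist() == [2.0, 2.5, 3.5]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sorted_columns_identical_and_idempotent(self, seed):
        m = random_matrix(30, 6, seed)
        out = quantile_normalize(m)
        x = out.values.to_numpy()
        sorted_cols = np.sort(x, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])
        assert np.allclose(x.mean(axis=0), x.mean(axis=0)[0])
        again = quantile_normalize(out)
        assert np.allclose(again.values.to_numpy(), x)

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(m)


class TestLog2Transform:
    def test_powers_of_two(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [8.0, 32.0], "b": [1.0, 2.0]}))
        out = log2_transform(m)
        assert out.values["a"].tolist() == [3.0, 5.0]
        assert out.scale == "log2"

    def test_round_trip_with_exp2(self):
        m = random_matrix(20, 4, 5)
        back = np.exp2(log2_transform(m).values.to_numpy())
        assert np.allclose(back, m.values.to_numpy())

    def test_nonpositive_values_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [0.0, 2.0], "b": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="positive"):
            log2_transform(m)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_quantile_normalization_equalizes_column_distributions(seed):
    out = quantile_normalize(random_matrix(15, 5, seed))
    sorted_cols = np.sort(out.values.to_numpy(), axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0]])


def test_zero_noise_pipeline_retains_exactly_the_expressed_probes():
    """With no noise and no absent calls, the dual rule keeps every expressed
    probe (tissue-restricted plus probes, planted bidirectional minus probes)
    and drops every floor-level probe."""
    cfg = SyntheticConfig(
        n_ucrs=20,
        n_groups=8,
        samples_per_group=3,
        noise_sd_log2=0.0,
        absent_rate=0.0,
        planted_bidirectional=["uc.3", "uc.17"],
        seed=21,
    )
    spots, _, _ = generate_dataset(cfg)
    res = preprocess_pipeline(spots, FilterParams(floor=cfg.detection_floor))
    expected = {f"uc.{i}-plus" for i in range(1, 21)} | {"uc.3-minus", "uc.17-minus"}
    assert set(res.retained) == expected
    assert res.log2.scale == "log2"
    # tie-averaging in quantile normalization preserves column sums, so the
    # heavily tied zero-noise columns still end up with a common mean
    x = res.normalized.values.to_numpy()
    assert np.allclose(x.mean(axis=0), x.mean(axis=0)[0])
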