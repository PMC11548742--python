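"""Variance prescreen, RF weighting, screening, cumulative sets, bank."""

import numpy as np
import pandas as pd
import pytest

from rampload import features
from rampload.features import (
    BankConfig,
    FeatureSet,
    build_cumulative_set,
    evaluate_classifier_bank,
    prescreen_low_variance,
    rank_feature_importance,
    screen_features,
)

# The 13 published indicator importances used for screening checks
# (time, fatigue occurrences, gaze-transfer, EAR/M/PERCLOS averages,
# AOI dwell percentages, blink count, respiratory rate).
PUBLISHED_IMPORTANCES = {
    "time": 0.599,
    "mild_occurrences": 0.203,
    "aoi_non_aoi_transfer_count": 0.049,
    "ear_avg": 0.047,
    "moderate_occurrences": 0.046,
    "pct_gaze_aoi0": 0.016,
    "m_avg": 0.014,
    "perclos_avg": 0.011,
    "blink_count": 0.006,
    "respiratory_rate": 0.002,
    "severe_occurrences": 0.002,
    "aoi_transfer_count": 0.002,
    "pct_gaze_aoi1": 0.001,
}


def indicator_frame(n=80, seed=0):
    rng = np.random.default_rng(seed)
    minutes = np.arange(1, n + 1)
    return pd.DataFrame({
        "subject_id": "S01",
        "minute": minutes,
        "ear_avg": rng.uniform(0.28, 0.34, n),
        "mild_occurrences": rng.integers(0, 3, n),
        "respiratory_rate": rng.uniform(12, 20, n),
        "respiratory_amplitude_avg": 1.0 + rng.normal(0, 0.001, n),
        "blink_count": rng.integers(10, 25, n),
    })


class TestPrescreen:
    def test_constant_column_dropped(self):
        df = indicator_frame()
        df["blink_count"] = 12
        retained = prescreen_low_variance(df, threshold=0.01)
        assert "blink_count" not in retained

    def test_threshold_zero_retains_everything(self):
        df = indicator_frame()
        df["blink_count"] = 12
        retained = prescreen_low_variance(df, threshold=0.0)
        assert "blink_count" in retained

    def test_stable_amplitude_dropped_varying_rate_kept(self):
        retained = prescreen_low_variance(indicator_frame(), threshold=0.05)
        assert "respiratory_amplitude_avg" not in retained
        assert "respiratory_rate" in retained

    def test_fatigue_metrics_always_survive(self):
        df = indicator_frame()
        df["ear_avg"] = 0.3  # constant, but a fatigue metric
        retained = prescreen_low_variance(df, threshold=0.05)
        assert "ear_avg" in retained

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            prescreen_low_variance(indicator_frame().iloc[:0])


class TestRankImportance:
    def separable_frame(self, n=120, seed=1):
        rng = np.random.default_rng(seed)
        labels = np.repeat(["low", "high"], n // 2)
        df = pd.DataFrame({
            "subject_id": np.tile(["S1", "S2"], n // 2),
            "minute": np.tile(np.arange(1, n // 2 + 1), 2),
            "ear_avg": np.where(labels == "high", 0.40, 0.30) + rng.normal(0, 0.005, n),
            "blink_count": rng.uniform(10, 20, n),
            "respiratory_rate": rng.uniform(12, 20, n),
        })
        return df, labels

    def test_separating_feature_ranks_first(self):
        df, labels = self.separable_frame()
        w = rank_feature_importance(df, labels, seed=0)
        assert w.index[0] == "ear_avg"

    def test_importances_normalized(self):
        df, labels = self.separable_frame()
        w = rank_feature_importance(df, labels, seed=0)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)
        assert (w >= 0).all()

    def test_deterministic_given_seed(self):
        df, labels = self.separable_frame()
        a = rank_feature_importance(df, labels, seed=3)
        b = rank_feature_importance(df, labels, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_single_class_rejected(self):
        df, _ = self.separable_frame()
        with pytest.raises(ValueError, match="two classes"):
            rank_feature_importance(df, np.repeat("low", len(df)), seed=0)


class TestScreenFeatures:
    def test_published_importances_wide_threshold_retains_eight(self):
        fs = screen_features(PUBLISHED_IMPORTANCES, 0.010)
        assert len(fs.columns) == 8
        assert fs.columns[:2] == ("time", "mild_occurrences")

    def test_published_importances_narrow_threshold_retains_five(self):
        fs = screen_features(PUBLISHED_IMPORTANCES, 0.040)
        assert fs.columns == (
            "time",
            "mild_occurrences",
            "aoi_non_aoi_transfer_count",
            "ear_avg",
            "moderate_occurrences",
        )

    def test_threshold_one_empties_the_set(self):
        assert screen_features(PUBLISHED_IMPORTANCES, 1.0).columns == ()

    def test_threshold_is_inclusive(self):
        fs = screen_features(PUBLISHED_IMPORTANCES, 0.011)
        assert "perclos_avg" in fs.columns

    def test_antitone_in_threshold(self):
        rng = np.random.default_rng(11)
        w = {f"f{i}": v for i, v in enumerate(rng.dirichlet(np.ones(15)))}
        previous = None
        for thr in np.linspace(0, 0.3, 20):
            cols = set(screen_features(w, thr).columns)
            if previous is not None:
                assert cols <= previous
            previous = cols


class TestCumulativeSet:
    def test_running_sum_per_subject(self):
        table = pd.DataFrame({
            "subject_id": ["A", "A", "A", "B", "B", "B"],
            "minute": [1, 2, 3, 1, 2, 3],
            "x": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0],
        })
        out, fs = build_cumulative_set(table, FeatureSet("base", ("x",)))
        assert list(out["cum_x"]) == [1.0, 3.0, 6.0, 5.0, 10.0, 15.0]
        assert fs.mode == "cumulative" and fs.columns == ("cum_x",)

    def test_one_cumulative_column_per_base_column(self):
        rng = np.random.default_rng(12)
        cols = [f"f{i}" for i in range(8)]
        table = pd.DataFrame(rng.uniform(size=(10, 8)), columns=cols)
        table.insert(0, "subject_id", "A")
        table.insert(1, "minute", np.arange(1, 11))
        _, fs = build_cumulative_set(table, FeatureSet("base", tuple(cols)))
        assert len(fs.columns) == 8

    def test_nonnegative_base_gives_nondecreasing_cumulative(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame({
            "subject_id": "A",
            "minute": np.arange(1, 31),
            "x": rng.uniform(0, 5, 30),
        })
        out, _ = build_cumulative_set(table, FeatureSet("base", ("x",)))
        assert (out["cum_x"].diff().dropna() >= 0).all()

    def test_unsorted_table_rejected(self):
        table = pd.DataFrame({
            "subject_id": ["A", "A"], "minute": [2, 1], "x": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="sorted"):
            build_cumulative_set(table, FeatureSet("base", ("x",)))


class TestModalSelection:
    def test_identical_repeats_report_that_repeat(self):
        pairs = [(0.97, 0.95)] * 10
        assert features._modal_pair(pairs) == (0.97, 0.95)

    def test_majority_wins(self):
        pairs = [(0.9, 0.9)] * 6 + [(0.8, 0.8)] * 4
        assert features._modal_pair(pairs) == (0.9, 0.9)

    def test_frequency_tie_goes_to_median_repeat(self):
        # two pairs appear twice each; (0.8, 0.8) occupies the middle
        pairs = [(0.9, 0.9), (0.8, 0.8), (0.8, 0.8), (0.9, 0.9), (0.7, 0.7)]
        assert features._modal_pair(pairs) == (0.8, 0.8)


def bank_frame(n=120, effect=4.0, seed=2):
    rng = np.random.default_rng(seed)
    minutes = np.tile(np.arange(1, n // 2 + 1), 2)
    labels = np.where(minutes > n // 4, "high", "low")
    x1 = rng.normal(0, 1, n) + effect * (labels == "high")
    x2 = rng.normal(0, 1, n)
    table = pd.DataFrame({
        "subject_id": np.repeat(["S1", "S2"], n // 2),
        "minute": minutes, "x1": x1, "x2": x2,
    })
    return table, labels


class TestClassifierBank:
    def test_all_ten_algorithms_reported_and_accurate_when_separable(self):
        table, labels = bank_frame()
        report = evaluate_classifier_bank(
            table, labels, FeatureSet("fs", ("x1", "x2", "minute")),
            BankConfig(seed=5, n_repeats=2),
        )
        assert sorted(report.index) == sorted(features.ALGORITHMS)
        assert report["cv_accuracy"].between(0, 1).all()
        assert (report["test_accuracy"] >= 0.9).all()

    def test_permuted_labels_score_near_chance(self):
        table, labels = bank_frame()
        rng = np.random.default_rng(6)
        permuted = rng.permutation(labels)
        report = evaluate_classifier_bank(
            table, permuted, FeatureSet("fs", ("x1", "x2")),
            BankConfig(seed=7, n_repeats=2),
        )
        assert 0.3 <= report["test_accuracy"].mean() <= 0.7

    def test_non_binary_labels_rejected(self):
        table, labels = bank_frame()
        with pytest.raises(ValueError, match="binary"):
            evaluate_classifier_bank(
                table, np.repeat("a", len(table)), FeatureSet("fs", ("x1",)),
                BankConfig(seed=1, n_repeats=1),
            )

    def test_missing_feature_column_rejected(self):
        table, labels = bank_frame()
        with pytest.raises(ValueError, match="not in table"):
            evaluate_classifier_bank(
                table, labels, FeatureSet("fs", ("nope",)), BankConfig(n_repeats=1)
            )
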