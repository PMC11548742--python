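"""End-to-end workload evaluation pipeline.

Chains the full analysis on one cohort: simulate (or load) frame
streams and sensor tables, run the fatigue engine, unitize to the
minute feature table, discover workload levels by clustering, weight
and screen features with a random forest, build the cumulative feature
set, optionally score the classifier bank, and produce the numerical
workload series with its low/high threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import features, labeling, scoring, synthetic, unitize
from .fatigue import process_stream
from .features import BankConfig, FeatureSet
from .scoring import ThresholdResult

__all__ = ["PipelineResult", "run_pipeline", "unitize_cohort"]


@dataclass
class PipelineResult:
    """Everything the pipeline produces, stage by stage."""

    config: synthetic.SimConfig
    feature_table: pd.DataFrame          # unitized minute table (720 rows by default)
    retained_columns: list[str]          # after variance prescreen
    labeled_table: pd.DataFrame          # + cluster_id, workload_level
    weights: pd.Series                   # RF importances, sum 1
    wide_set: FeatureSet                 # importance >= 0.010, raw
    narrow_set: FeatureSet               # importance >= 0.040, raw
    cumulative_set: FeatureSet           # cumulative images of the wide set
    cumulative_table: pd.DataFrame       # labeled table + cum_ columns
    workload: pd.DataFrame               # subject, minute, workload, grade
    threshold: ThresholdResult
    reports: dict = field(default_factory=dict)  # feature-set name -> AccuracyReport


def unitize_cohort(
    streams: dict[str, pd.DataFrame],
    minute_table: pd.DataFrame,
    fps: float,
    duration_min: int,
    impute_seed: int = 0,
) -> pd.DataFrame:
    """Fatigue engine + minute aggregation for every subject."""
    sessions = {}
    for sid, stream in streams.items():
        log, state = process_stream(stream, fps=fps)
        sessions[sid] = unitize.aggregate_session(
            log, state.event_log, fps=fps, n_minutes=duration_min
        )
    return unitize.build_feature_table(sessions, minute_table, impute_seed=impute_seed)


def run_pipeline(
    config: synthetic.SimConfig,
    prescreen_cv: float = 0.05,
    k_range: tuple[int, int] = labeling.DEFAULT_K_RANGE,
    wide_threshold: float = features.SCREEN_THRESHOLD_WIDE,
    narrow_threshold: float = features.SCREEN_THRESHOLD_NARROW,
    classify: bool = False,
    bank_config: BankConfig | None = None,
) -> PipelineResult:
    """Run the whole pipeline on a synthetic cohort.

    All stage seeds derive from ``config.seed``. Classifier-bank
    evaluation is opt-in (``classify=True``) since it dominates the
    runtime; it then scores the wide, narrow and cumulative feature
    sets.
    """
    seed = int(config.seed) & 0x7FFFFFFF
    streams, minute_table = synthetic.simulate_cohort(config)
    table = unitize_cohort(
        streams, minute_table, fps=config.fps, duration_min=config.duration_min,
        impute_seed=seed,
    )

    retained = features.prescreen_low_variance(table, threshold=prescreen_cv)
    labeled = labeling.label_cohort(table, k_range=k_range, seed=seed, include=retained)
    labels = labeled["workload_level"].to_numpy()

    weights = features.rank_feature_importance(labeled, labels, seed=seed)
    wide = features.screen_features(weights, wide_threshold)
    narrow = features.screen_features(weights, narrow_threshold)
    cum_table, cum_set = features.build_cumulative_set(labeled, wide)

    workload, threshold = scoring.build_workload_series(cum_table, cum_set, weights, labels)

    reports = {}
    if classify:
        bank = bank_config or BankConfig(seed=seed)
        reports["wide"] = features.evaluate_classifier_bank(cum_table, labels, wide, bank)
        reports["narrow"] = features.evaluate_classifier_bank(cum_table, labels, narrow, bank)
        reports["cumulative"] = features.evaluate_classifier_bank(cum_table, labels, cum_set, bank)

    return PipelineResult(
        config=config,
        feature_table=table,
        retained_columns=retained,
        labeled_table=labeled,
        weights=weights,
        wide_set=wide,
        narrow_set=narrow,
        cumulative_set=cum_set,
        cumulative_table=cum_table,
        workload=workload,
        threshold=threshold,
        reports=reports,
    )
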