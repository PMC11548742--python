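"""Numerical workload scoring and level-threshold enumeration.

Each minute's workload is the importance-weighted sum of its optimal
feature set, W = sum_i c_i * V_i, where c_i is the random-forest
importance of feature i and V_i its (possibly cumulative) value; a
cumulative feature inherits the weight of the base feature it
accumulates. W is kept on the raw weighted-sum scale — the absolute
value is the deliverable, since a shift's maximum workload is unknown
to the operator.

The boundary between low and high workload is found by mirrored
percentile matching within the clusters' overlap: for a percentage p
scanned over 5-10% in 0.1% steps, take the low cluster's p-th
percentile from the top and the high cluster's p-th percentile from the
bottom (nearest-rank), and keep the p whose two boundary values are
closest. The integer threshold is the midpoint of that pair rounded
half-up.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import CUMULATIVE_PREFIX, FeatureSet
from .indicators import SUBJECT_COLUMN, TIME_COLUMN

__all__ = [
    "ThresholdResult",
    "compute_workload",
    "compute_workload_series",
    "enumerate_threshold",
    "select_integer_threshold",
    "grade_workload",
]

P_RANGE = (0.05, 0.10)
P_STEP = 0.001


def _weight_for(column: str, weights: Mapping[str, float]) -> float:
    """Weight of a feature column; cumulative columns inherit their base's."""
    name = column[len(CUMULATIVE_PREFIX):] if column.startswith(CUMULATIVE_PREFIX) else column
    try:
        return float(weights[name])
    except KeyError:
        raise KeyError(f"no importance weight for feature {column!r}") from None


def compute_workload(values: Mapping[str, float], weights: Mapping[str, float]) -> float:
    """W = sum_i c_i * V_i over one minute's feature vector."""
    return float(sum(_weight_for(col, weights) * float(v) for col, v in values.items()))


def compute_workload_series(
    table: pd.DataFrame, feature_set: FeatureSet, weights: Mapping[str, float]
) -> pd.Series:
    """Vectorized per-row workload over a feature table."""
    w = np.array([_weight_for(c, weights) for c in feature_set.columns])
    x = table[list(feature_set.columns)].to_numpy(dtype=float)
    return pd.Series(x @ w, index=table.index, name="workload")


def _nearest_rank(p: float, n: int) -> int:
    # epsilon guards against float noise like 0.07 * 100 = 7.000000000000001
    return max(1, math.ceil(p * n - 1e-9))


def _rank_from_bottom(sorted_values: np.ndarray, p: float) -> float:
    """Nearest-rank p-th percentile from the bottom of an ascending sort."""
    rank = _nearest_rank(p, len(sorted_values))
    return float(sorted_values[rank - 1])


def _rank_from_top(sorted_values: np.ndarray, p: float) -> float:
    """Nearest-rank p-th percentile from the top (upper-tail boundary)."""
    n = len(sorted_values)
    rank = _nearest_rank(p, n)
    return float(sorted_values[n - rank])


@dataclass(frozen=True)
class ThresholdResult:
    """Matched mirrored-percentile boundary between the two clusters."""

    p: float          # matched percentage (NaN when clusters are disjoint)
    v_low: float      # low cluster's boundary value (p-th from the top)
    v_high: float     # high cluster's boundary value (p-th from the bottom)

    @property
    def threshold(self) -> int:
        return select_integer_threshold(self.v_low, self.v_high)

    def __iter__(self):
        return iter((self.p, self.v_low, self.v_high))


def enumerate_threshold(
    low_values,
    high_values,
    p_range: tuple[float, float] = P_RANGE,
    step: float = P_STEP,
) -> ThresholdResult:
    """Scan mirrored percentiles for the closest boundary pair.

    ``low_values`` / ``high_values`` are the workload samples of the
    low- and high-workload clusters. For each p on the grid, the low
    cluster contributes its p-th percentile from the top and the high
    cluster its p-th percentile from the bottom (nearest-rank); the p
    minimizing |v_low - v_high| wins, ties to the smallest p. If the
    clusters do not overlap at all, the gap endpoints are returned with
    a warning (their midpoint is the natural threshold).
    """
    low = np.sort(np.asarray(low_values, dtype=float))
    high = np.sort(np.asarray(high_values, dtype=float))
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both clusters must be nonempty")
    if low[-1] < high[0]:
        warnings.warn(
            "clusters are disjoint; falling back to the midpoint of the gap",
            stacklevel=2,
        )
        return ThresholdResult(float("nan"), float(low[-1]), float(high[0]))
    n_steps = int(round((p_range[1] - p_range[0]) / step))
    best = None
    for i in range(n_steps + 1):
        p = round(p_range[0] + i * step, 10)
        v_low = _rank_from_top(low, p)
        v_high = _rank_from_bottom(high, p)
        gap = abs(v_low - v_high)
        if best is None or gap < best[0]:
            best = (gap, p, v_low, v_high)
    return ThresholdResult(best[1], best[2], best[3])


def select_integer_threshold(v_low: float, v_high: float) -> int:
    """Integer threshold: midpoint of the boundary pair, half rounded up."""
    if not (math.isfinite(v_low) and math.isfinite(v_high)):
        raise ValueError("boundary values must be finite")
    return int(math.floor((v_low + v_high) / 2.0 + 0.5))


def grade_workload(workload, threshold: float):
    """Grade workload values: 'high' iff W >= threshold."""
    w = np.asarray(workload, dtype=float)
    grades = np.where(w >= threshold, "high", "low")
    return grades if w.ndim else str(grades)


def build_workload_series(
    table: pd.DataFrame,
    feature_set: FeatureSet,
    weights: Mapping[str, float],
    levels: pd.Series | np.ndarray,
) -> tuple[pd.DataFrame, ThresholdResult]:
    """End-of-pipeline convenience: score, threshold and grade a cohort.

    ``levels`` holds the cluster-derived 'low'/'high' labels used to
    split the workload samples for threshold enumeration. Returns the
    per-minute series (subject, minute, workload, grade) and the
    threshold result.
    """
    w = compute_workload_series(table, feature_set, weights)
    levels = np.asarray(levels)
    result = enumerate_threshold(w[levels == "low"], w[levels == "high"])
    series = pd.DataFrame(
        {
            SUBJECT_COLUMN: table[SUBJECT_COLUMN].to_numpy(),
            TIME_COLUMN: table[TIME_COLUMN].to_numpy(),
            "workload": w.to_numpy(),
            "grade": grade_workload(w.to_numpy(), result.threshold),
        }
    )
    return series, result
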