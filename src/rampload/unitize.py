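"""Minute-level unitization of frame streams and sensor tables.

Converts the fatigue engine's per-frame log and the eye-movement /
respiration sensor table into one feature row per subject-minute
carrying the full indicator set (see :mod:`rampload.indicators`).

Missing-data policy for the frame-derived metrics (EAR/PERCLOS/M
averages): if a minute lost fewer than 50% of its frames, the surviving
valid frames are averaged; at 50% or more the minute's value is imputed
by a random-forest regression trained on the complete minutes (using
the minute index and the sensor indicators as predictors), clamped to
the column's observed range, and blended with the surviving valid
frames weighted by frame share. Fatigue-occurrence counts ignore
missing frames entirely: a run is counted in the minute where it
terminates.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .fatigue import FatigueEvent, FatigueLevel
from .indicators import (
    INDICATOR_COLUMNS,
    SENSOR_COLUMNS,
    SUBJECT_COLUMN,
    TIME_COLUMN,
)

__all__ = [
    "aggregate_minute",
    "count_level_occurrences",
    "aggregate_session",
    "build_feature_table",
    "impute_high_missing_minutes",
]

MISSING_IMPUTE_FRACTION = 0.5

_LEVEL_COLUMNS = {
    FatigueLevel.MILD: "mild_occurrences",
    FatigueLevel.MODERATE: "moderate_occurrences",
    FatigueLevel.SEVERE: "severe_occurrences",
}


def aggregate_minute(minute_log: pd.DataFrame) -> tuple[float, float, float, float]:
    """Average EAR/PERCLOS/M over one minute's valid frames.

    Returns ``(ear_avg, perclos_avg, m_avg, missing_fraction)``. With at
    least one valid frame the averages run over valid frames only; with
    none they are NaN (to be imputed). Raises on an empty minute.
    """
    if len(minute_log) == 0:
        raise ValueError("minute contains no frames")
    valid = minute_log["valid"].to_numpy(dtype=bool)
    missing_fraction = 1.0 - valid.mean()
    if valid.any():
        sub = minute_log.loc[valid]
        ear = float(sub["ear"].mean())
        perclos = float(sub["perclos"].mean())
        m = float(sub["m"].mean())
    else:
        ear = perclos = m = float("nan")
    return ear, perclos, m, float(missing_fraction)


def count_level_occurrences(
    events: Sequence[FatigueEvent], n_minutes: int, fps: float = 30.0
) -> pd.DataFrame:
    """Per-minute fatigue-occurrence counts from the engine event log.

    A run is attributed to the minute containing its termination frame;
    runs spanning a minute boundary therefore count once, in the minute
    where they end. Events beyond ``n_minutes`` are folded into the last
    minute (a run closed exactly at session end).
    """
    counts = pd.DataFrame(
        0,
        index=pd.RangeIndex(1, n_minutes + 1, name=TIME_COLUMN),
        columns=list(_LEVEL_COLUMNS.values()),
        dtype=np.int64,
    )
    frames_per_min = int(round(60 * fps))
    for ev in events:
        if ev.kind != "occurrence":
            continue
        minute = min(int(ev.frame_index // frames_per_min) + 1, n_minutes)
        counts.loc[minute, _LEVEL_COLUMNS[ev.level]] += 1
    return counts.reset_index()


def aggregate_session(
    log: pd.DataFrame, events: Sequence[FatigueEvent], fps: float = 30.0,
    n_minutes: int | None = None,
) -> pd.DataFrame:
    """Unitize one subject's engine output to per-minute fatigue metrics.

    Returns columns ``minute, ear_avg, perclos_avg, m_avg,
    mild/moderate/severe_occurrences, alarm, missing_fraction``.
    """
    frames_per_min = int(round(60 * fps))
    minute = (log["frame_index"] // frames_per_min).astype(int) + 1
    if n_minutes is None:
        n_minutes = int(minute.max())

    grouped = log.groupby(minute)
    rows = []
    for m_idx, sub in grouped:
        if m_idx > n_minutes:
            continue
        ear, perclos, mval, miss = aggregate_minute(sub)
        rows.append(
            {
                TIME_COLUMN: int(m_idx),
                "ear_avg": ear,
                "perclos_avg": perclos,
                "m_avg": mval,
                "alarm": bool(sub["alarm"].any()),
                "missing_fraction": miss,
            }
        )
    fat = pd.DataFrame(rows)
    occ = count_level_occurrences(events, n_minutes, fps=fps)
    out = occ.merge(fat, on=TIME_COLUMN, how="left", validate="1:1")
    if out["ear_avg"].isna().all():
        raise ValueError("session log produced no valid minutes")
    return out


def impute_high_missing_minutes(
    table: pd.DataFrame,
    targets: Sequence[str] = ("ear_avg", "perclos_avg", "m_avg"),
    threshold: float = MISSING_IMPUTE_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute frame-derived averages for minutes with heavy frame loss.

    Minutes with ``missing_fraction >= threshold`` get each target
    predicted by a random forest trained on the remaining minutes
    (predictors: minute index plus the sensor indicators), clipped to
    the column's observed range, then blended with the minute's own
    valid-frame average weighted by the surviving frame share.
    """
    out = table.copy()
    heavy = out["missing_fraction"].to_numpy() >= threshold
    if not heavy.any():
        return out
    predictors = [TIME_COLUMN] + [c for c in SENSOR_COLUMNS if c in out.columns]
    x_all = out[predictors].to_numpy(dtype=float)
    for t_idx, target in enumerate(targets):
        y = out[target].to_numpy(dtype=float)
        train = ~heavy & np.isfinite(y)
        if train.sum() < 2:
            raise ValueError(f"not enough complete minutes to impute {target}")
        model = RandomForestRegressor(
            n_estimators=200, random_state=(int(seed) + t_idx) & 0x7FFFFFFF
        )
        model.fit(x_all[train], y[train])
        pred = model.predict(x_all[heavy])
        lo, hi = np.nanmin(y[train]), np.nanmax(y[train])
        pred = np.clip(pred, lo, hi)  # automated plausibility clamp
        observed = y[heavy]
        miss = out.loc[heavy, "missing_fraction"].to_numpy()
        blended = np.where(
            np.isfinite(observed), miss * pred + (1.0 - miss) * observed, pred
        )
        y[heavy] = blended
        out[target] = y
    return out


def build_feature_table(
    session_outputs: Mapping[str, pd.DataFrame],
    minute_table: pd.DataFrame,
    impute_seed: int = 0,
) -> pd.DataFrame:
    """Assemble the cohort's unified minute feature table.

    ``session_outputs`` maps subject id to the per-minute fatigue table
    from :func:`aggregate_session`; ``minute_table`` is the sensor
    indicator table (one row per subject-minute). Output: one row per
    subject-minute, sorted by (subject, minute), with the full indicator
    set, the ``alarm`` flag, ``missing_fraction`` and any ground-truth
    columns carried through. Raises on a span mismatch between sources.
    """
    frames = []
    for sid, fat in session_outputs.items():
        sub = minute_table[minute_table[SUBJECT_COLUMN] == sid]
        if len(sub) == 0:
            raise ValueError(f"no minute indicators for subject {sid!r}")
        if set(sub[TIME_COLUMN]) != set(fat[TIME_COLUMN]):
            raise ValueError(f"minute span mismatch for subject {sid!r}")
        merged = sub.merge(fat, on=TIME_COLUMN, how="inner", validate="1:1")
        frames.append(merged)
    missing_subjects = set(minute_table[SUBJECT_COLUMN]) - set(session_outputs)
    if missing_subjects:
        raise ValueError(f"no frame outputs for subjects {sorted(missing_subjects)}")
    table = pd.concat(frames, ignore_index=True)
    table = impute_high_missing_minutes(table, seed=impute_seed)
    ordered = (
        [SUBJECT_COLUMN, TIME_COLUMN]
        + INDICATOR_COLUMNS
        + ["alarm", "missing_fraction"]
        + [c for c in table.columns if c.startswith("true_")]
    )
    table = table[[c for c in ordered if c in table.columns]]
    table = table.sort_values([SUBJECT_COLUMN, TIME_COLUMN], kind="mergesort").reset_index(
        drop=True
    )
    if table[INDICATOR_COLUMNS].isna().any().any():
        raise ValueError("indicator table still contains NaN after imputation")
    return table
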