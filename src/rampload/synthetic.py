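"""Synthetic cohort generator.

Emulates the data produced by a ramp-controller simulation session:
per-subject camera frame streams carrying an eye-aspect-ratio (EAR)
signal with blinks, prolonged-closure fatigue episodes and dropped
frames, plus a per-minute table of eye-movement and respiration
indicators with a two-regime (early low workload / late high workload)
temporal structure.

The generator is the test bed for every downstream stage: the frame
streams feed the fatigue engine, the minute table feeds unitization,
labeling and classification. Ground-truth regime labels are stored in
the minute table (``true_regime``) for recovery tests only — no
analysis stage may read them.

Fatigue episodes are produced mechanistically: a contiguous eye-closure
segment long enough that the 300-frame PERCLOS window saturates and the
fused metric M = 0.3*EAR + 0.7*PERCLOS crosses the 0.605 run criterion.
Episode lengths are calibrated from a requested M-run length by
inverting that window dynamics (see :func:`_closure_length_for_run`).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicators import SENSOR_COLUMNS, SUBJECT_COLUMN, TIME_COLUMN

__all__ = [
    "SimConfig",
    "simulate_frame_stream",
    "inject_missing",
    "simulate_cohort",
    "FRAME_COLUMNS",
]

FRAME_COLUMNS = ["subject_id", "frame_index", "timestamp_s", "ear", "valid"]

#: Default distribution over M-run lengths (frames) of fatigue episodes:
#: mostly mild runs, some moderate, a few severe (>= 50 triggers the alarm).
DEFAULT_EPISODE_RUN_LENGTHS: dict[int, float] = {8: 0.7, 25: 0.25, 60: 0.05}

#: Microsleep closures per minute at full drowsiness severity.
MICROSLEEP_RATE_MAX = 8.0

# Per-minute means / within-regime sd / standardized regime shift sign for
# each sensor indicator. Workload-sensitive indicators shift between the
# two regimes by effect_size * sd; the remainder are stable low-variation
# channels (they are what the variance prescreen is meant to drop).
_SENSOR_MODEL: dict[str, tuple[float, float, int]] = {
    "pupil_diameter_avg": (2.5, 0.05, 0),
    "blink_count": (15.0, 2.0, +1),
    "gaze_duration_avg": (55_000.0, 1_500.0, 0),
    "sweep_length_avg": (158.0, 4.0, 0),
    "gaze_point_count": (103.0, 2.0, 0),
    "sweep_count": (101.0, 2.0, 0),
    "gaze_duration_avg_alt": (52_000.0, 1_400.0, 0),
    "sweep_duration_avg": (83.0, 1.5, 0),
    "aoi_gaze_duration_avg": (45_000.0, 1_200.0, 0),
    "pct_gaze_aoi0": (0.62, 0.05, +1),
    "pct_gaze_aoi1": (0.20, 0.03, -1),
    "aoi_transfer_count": (30.0, 5.0, +1),
    "aoi_non_aoi_transfer_count": (20.0, 4.0, +1),
    "respiratory_rate": (16.0, 1.5, +1),
    "respiratory_amplitude_avg": (1.0, 0.01, 0),
}

_INTEGER_SENSORS = {
    "blink_count",
    "gaze_point_count",
    "sweep_count",
    "aoi_transfer_count",
    "aoi_non_aoi_transfer_count",
}


def _resolve_schedule(value, duration_min: int, name: str) -> np.ndarray:
    """Expand a per-minute schedule.

    Accepts a scalar (constant), a ``(start, stop)`` pair (linear ramp
    over the session) or a full per-minute sequence.
    """
    if np.isscalar(value):
        out = np.full(duration_min, float(value))
    else:
        seq = np.asarray(value, dtype=float)
        if seq.ndim != 1:
            raise ValueError(f"{name}: schedule must be scalar, pair or 1-D sequence")
        if seq.size == 2 and duration_min != 2:
            out = np.linspace(seq[0], seq[1], duration_min)
        elif seq.size == duration_min:
            out = seq.copy()
        else:
            raise ValueError(
                f"{name}: schedule length {seq.size} != duration_min {duration_min}"
            )
    if (out < 0).any():
        raise ValueError(f"{name}: rates must be nonnegative")
    return out


@dataclass(frozen=True)
class SimConfig:
    """Study-session configuration.

    Defaults describe one simulated shift: 8 subjects observed for 90
    minutes at 30 frames/s, a resting EAR of 0.32, ~6% dropped frames,
    and a workload regime change near minute 45 with +/-10 minutes of
    per-subject jitter so the two regimes overlap in clock time.
    """

    n_subjects: int = 8
    duration_min: int = 90
    fps: int = 30
    baseline_ear: float = 0.32
    #: blinks/minute; scalar, (start, stop) ramp, or per-minute sequence.
    blink_rate: float | Sequence[float] = 15.0
    #: fatigue episodes/minute; must be nondecreasing over the session.
    fatigue_episode_rate: float | Sequence[float] = (0.05, 0.5)
    #: distribution over target M-run lengths (frames) per episode.
    episode_length_frames: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EPISODE_RUN_LENGTHS)
    )
    missing_rate: float = 0.06
    regime_change_min: int = 45
    regime_jitter_min: int = 10
    #: standardized mean shift of workload-sensitive indicators between regimes.
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.baseline_ear <= 0.25:
            raise ValueError("baseline_ear must exceed the 0.25 blink criterion")
        if self.regime_jitter_min < 0:
            raise ValueError("regime_jitter_min must be nonnegative")
        self.blink_schedule()  # validates nonnegativity/shape
        ep = self.episode_rate_schedule()
        if (np.diff(ep) < -1e-12).any():
            raise ValueError("fatigue_episode_rate must be nondecreasing over time")
        if self.episode_length_frames:
            lengths = np.array(list(self.episode_length_frames), dtype=float)
            probs = np.array(list(self.episode_length_frames.values()), dtype=float)
            if (lengths <= 0).any() or (probs < 0).any() or probs.sum() <= 0:
                raise ValueError("episode_length_frames: lengths > 0, probs >= 0 required")

    # -- schedules ---------------------------------------------------------

    def blink_schedule(self) -> np.ndarray:
        return _resolve_schedule(self.blink_rate, self.duration_min, "blink_rate")

    def episode_rate_schedule(self) -> np.ndarray:
        return _resolve_schedule(
            self.fatigue_episode_rate, self.duration_min, "fatigue_episode_rate"
        )

    @property
    def n_frames(self) -> int:
        return self.duration_min * 60 * self.fps

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        kw = dict(mapping)
        if "episode_length_frames" in kw and kw["episode_length_frames"] is not None:
            kw["episode_length_frames"] = {
                int(k): float(v) for k, v in dict(kw["episode_length_frames"]).items()
            }
        return cls(**kw)


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    """Independent, reproducible generator for one named substream."""
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def _closure_length_for_run(
    run_frames: int, baseline_ear: float, closed_ear: float, background_closed: float = 0.0
) -> int:
    """Closure length (frames) producing an M-run of about ``run_frames``.

    With a 300-frame PERCLOS window, a closure of length L yields
    M > 0.605 while the closed-frame count c in the window satisfies
    0.3*EAR + 0.7*c/300 > 0.605. During the closure (EAR = closed_ear) and
    after it (EAR back at baseline) the critical counts differ, which is
    what this inversion accounts for. ``background_closed`` is the
    expected count of blink/microsleep-closed frames already in the
    window, which lowers the closure length the episode itself must
    contribute. The calibration is intentionally coarse.
    """
    c_during = int(np.ceil((0.605 - 0.3 * closed_ear) * 300 / 0.7))  # c required while closed
    c_after = int(np.ceil((0.605 - 0.3 * baseline_ear) * 300 / 0.7))  # c required when reopened
    b = int(round(max(0.0, background_closed)))
    c_during = max(1, c_during - b)
    c_after = max(1, c_after - b)
    # Run segments: during closure, frames with c >= c_during (c ramps 1..min(L,300));
    # after closure, frames while c = L - s >= c_after (L <= 300) or c = 300 - s.
    r = int(run_frames)
    short_max = 300 - c_after  # run achievable with L <= c_during (post-closure only)
    if r <= short_max and r + c_after - 1 <= c_during:
        return r + c_after - 1
    # both segments active, L <= 300: r = (L - c_during + 1) + (L - c_after + 1)
    L = int(np.ceil((r + c_during + c_after - 2) / 2))
    if L <= 300:
        return max(L, c_during)
    # saturated window, L > 300: r = (L - c_during + 1) + (300 - c_after + 1)
    return r + c_during + c_after - 302


def simulate_frame_stream(config: SimConfig, subject_id: str) -> pd.DataFrame:
    """Simulate one subject's camera frame stream (all frames valid).

    Returns a frame table (``subject_id, frame_index, timestamp_s, ear,
    valid``) of exactly ``duration_min * 60 * fps`` rows. Baseline frames
    keep EAR >= 0.25 (above the blink criterion); blinks are rectangular
    dips of 3-8 frames to EAR in [0.05, 0.2]; fatigue episodes are long
    closures engineered so the fused metric M exceeds 0.605 downstream.
    """
    sid_list = config.subject_ids()
    try:
        subj_idx = sid_list.index(subject_id)
    except ValueError:
        # external id: hash to a stable substream
        subj_idx = abs(hash(subject_id)) % (2**20) + config.n_subjects
    rng = _rng(config, 1, subj_idx)

    n = config.n_frames
    frames_per_min = 60 * config.fps
    noise_amp = min(0.015, config.baseline_ear - 0.25)
    ear = config.baseline_ear + rng.uniform(-noise_amp, noise_amp, size=n)

    blink_rate = config.blink_schedule()
    ep_rate = config.episode_rate_schedule()
    # Drowsiness severity in [0, 1] tracks the (nondecreasing) episode-rate
    # schedule; it drives the microsleep density so that minute-level
    # eye-closure rises smoothly over the session, the way sustained
    # fatigue manifests, rather than only in isolated spikes.
    rate_max = float(ep_rate.max())
    drowsiness = ep_rate / rate_max if rate_max > 0 else np.zeros_like(ep_rate)
    microsleep_rate = MICROSLEEP_RATE_MAX * drowsiness  # events/minute
    ms_mean_len = 25.0  # frames; lengths drawn uniform 10..40
    # expected blink/microsleep-closed frames inside a 300-frame window
    background = (blink_rate * 5.5 + microsleep_rate * ms_mean_len) * (300.0 / frames_per_min)

    episode_mask = np.zeros(n, dtype=bool)
    order = np.argsort(list(config.episode_length_frames))
    run_lengths = np.array(list(config.episode_length_frames), dtype=int)[order]
    run_probs = np.array(list(config.episode_length_frames.values()), dtype=float)[order]
    if run_probs.size:
        run_probs = run_probs / run_probs.sum()
        run_cum = np.cumsum(run_probs)

    # Fatigue episodes: Poisson counts per minute at a nondecreasing rate,
    # placed with a guard gap so PERCLOS windows of neighbouring episodes
    # do not interact.
    episode_intervals: list[tuple[int, int]] = []
    guard = 400
    for minute in range(config.duration_min):
        for _ in range(rng.poisson(ep_rate[minute])):
            if run_lengths.size == 0:
                break
            # episode depth deepens with drowsiness: long (severe) runs
            # require deep drowsiness, moderate runs at least some — a
            # length drawn above the current depth ceiling is downgraded
            idx = min(int(np.searchsorted(run_cum, rng.random(), side="right")),
                      len(run_lengths) - 1)
            depth_ceiling = int(np.searchsorted([0.3, 0.7], drowsiness[minute], side="right"))
            if len(run_lengths) > 2:
                idx = min(idx, int(round(depth_ceiling * (len(run_lengths) - 1) / 2)))
            else:
                idx = min(idx, depth_ceiling)
            target_run = int(run_lengths[idx])
            length = _closure_length_for_run(
                target_run, config.baseline_ear, 0.085, background[minute]
            )
            start = int(rng.integers(minute * frames_per_min, (minute + 1) * frames_per_min))
            end = min(start + length, n)
            if any(start < e + guard and s < end + guard for s, e in episode_intervals):
                continue
            episode_intervals.append((start, end))
            episode_mask[start:end] = True
            ear[start:end] = rng.uniform(0.05, 0.12, size=end - start)

    # Blinks: short rectangular dips outside episodes. Microsleeps are
    # longer closures whose density follows the drowsiness severity.
    for minute in range(config.duration_min):
        for _ in range(rng.poisson(blink_rate[minute])):
            length = int(rng.integers(3, 9))
            start = int(rng.integers(minute * frames_per_min, (minute + 1) * frames_per_min))
            end = min(start + length, n)
            if episode_mask[start:end].any():
                continue
            ear[start:end] = rng.uniform(0.05, 0.2, size=end - start)
        for _ in range(rng.poisson(microsleep_rate[minute])):
            length = int(rng.integers(10, 41))
            start = int(rng.integers(minute * frames_per_min, (minute + 1) * frames_per_min))
            end = min(start + length, n)
            if episode_mask[start:end].any():
                continue
            ear[start:end] = rng.uniform(0.05, 0.2, size=end - start)

    idx = np.arange(n)
    return pd.DataFrame(
        {
            "subject_id": np.repeat(subject_id, n),
            "frame_index": idx,
            "timestamp_s": idx / config.fps,
            "ear": ear,
            "valid": np.ones(n, dtype=bool),
        }
    )


def inject_missing(stream: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mark frames invalid independently with probability ``rate``.

    Invalid frames get ``valid = False`` and a NaN EAR sentinel; row count
    and order are preserved. Emulates detection omissions of the face
    tracker (the study setting loses roughly 6% of frames).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = stream.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    drop = rng.random(len(out)) < rate
    out.loc[drop, "valid"] = False
    out.loc[drop, "ear"] = np.nan
    return out


def _simulate_minute_indicators(config: SimConfig) -> pd.DataFrame:
    """Per-minute sensor indicator table with the two-regime structure."""
    rng = _rng(config, 2)
    rows = []
    for sid in config.subject_ids():
        jitter = (
            int(rng.integers(-config.regime_jitter_min, config.regime_jitter_min + 1))
            if config.regime_jitter_min > 0
            else 0
        )
        change = int(np.clip(config.regime_change_min + jitter, 1, config.duration_min))
        minutes = np.arange(1, config.duration_min + 1)
        regime = (minutes > change).astype(int)
        data = {SUBJECT_COLUMN: sid, TIME_COLUMN: minutes, "true_regime": regime}
        for col in SENSOR_COLUMNS:
            mean, sd, sign = _SENSOR_MODEL[col]
            shift = sign * config.effect_size * sd
            values = rng.normal(mean + shift * regime, sd)
            if col in _INTEGER_SENSORS:
                values = np.maximum(np.rint(values), 0)
            elif col.startswith("pct_"):
                values = np.clip(values, 0.01, 0.97)
            else:
                values = np.maximum(values, 1e-3)
            data[col] = values
        df = pd.DataFrame(data)
        # keep the two AOI dwell fractions jointly feasible
        total = df["pct_gaze_aoi0"] + df["pct_gaze_aoi1"]
        over = total > 0.98
        if over.any():
            scale = 0.98 / total[over]
            df.loc[over, "pct_gaze_aoi0"] *= scale
            df.loc[over, "pct_gaze_aoi1"] *= scale
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: SimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate the full cohort.

    Returns ``(streams, minute_table)`` where ``streams`` maps subject id
    to its frame table (dropped frames already injected at
    ``config.missing_rate``) and ``minute_table`` holds one row per
    subject-minute with the eye-movement and respiration indicators, the
    1-based ``minute`` index and the ground-truth ``true_regime`` column
    (0 = early/low, 1 = late/high; reserved for recovery tests).
    """
    streams: dict[str, pd.DataFrame] = {}
    for s_idx, sid in enumerate(config.subject_ids()):
        stream = simulate_frame_stream(config, sid)
        miss_seed = int(_rng(config, 3, s_idx).integers(0, 2**31 - 1))
        streams[sid] = inject_missing(stream, config.missing_rate, miss_seed)
    minute_table = _simulate_minute_indicators(config)
    return streams, minute_table


def write_cohort_csv(streams: Mapping[str, pd.DataFrame], minute_table: pd.DataFrame, out_dir) -> None:
    """Write frame streams and the minute indicator table as CSV files."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, df in streams.items():
        df.to_csv(out / f"frames_{sid}.csv", index=False)
    minute_table.to_csv(out / "minute_indicators.csv", index=False)
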