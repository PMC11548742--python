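"""Frame-level fatigue engine.

Implements the ocular fatigue chain used for real-time monitoring of
ramp controllers:

* **EAR** — eye aspect ratio from six eye landmarks,
  ``(|p2-p6| + |p3-p5|) / (2 |p1-p4|)``; drops toward 0 as the eye
  closes. The engine equally accepts precomputed EAR streams, so
  landmark detection is optional.
* **PERCLOS** — fraction of frames with EAR strictly below 0.3 within a
  sliding window of the last 300 frames. During warm-up the partial
  window is used; invalid (dropped) frames are excluded from both the
  numerator and the denominator.
* **M** — fused ocular metric ``0.3*EAR + 0.7*PERCLOS``.
* **Fatigue runs** — a run is a maximal streak of consecutive frames
  with M > 0.605; its length N grades the episode (5 < N <= 15 mild,
  15 < N < 50 moderate, N >= 50 severe) and the alarm is active while
  N >= 50. An occurrence is recorded at the frame where the run
  terminates (or at stream end).

Dropped frames inside a run do not fabricate closures: up to four
consecutive invalid frames carry the last M forward; a fifth
consecutive invalid frame closes the run.
"""

from __future__ import annotations

import enum
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EAR_CLOSURE_THRESHOLD",
    "PERCLOS_WINDOW",
    "M_RUN_THRESHOLD",
    "ALARM_RUN_LENGTH",
    "FatigueLevel",
    "FatigueEvent",
    "FatigueState",
    "compute_ear",
    "compute_perclos",
    "fuse_m",
    "classify_fatigue_level",
    "step_fatigue_state",
    "process_stream",
]

EAR_CLOSURE_THRESHOLD = 0.3   # strict: EAR < 0.3 counts as closed
PERCLOS_WINDOW = 300          # frames
M_EAR_WEIGHT = 0.3
M_PERCLOS_WEIGHT = 0.7
M_RUN_THRESHOLD = 0.605       # strict: M > 0.605 extends a run
ALARM_RUN_LENGTH = 50         # inclusive: N >= 50 -> severe + alarm
MAX_CARRIED_INVALID = 4       # a 5th consecutive invalid frame closes the run


class FatigueLevel(enum.IntEnum):
    """Ordered fatigue grade of a completed M-run of length N."""

    NONE = 0      # N <= 5
    MILD = 1      # 5 < N <= 15
    MODERATE = 2  # 15 < N < 50
    SEVERE = 3    # N >= 50


def compute_ear(landmarks) -> float:
    """Eye aspect ratio from six landmarks.

    ``landmarks`` is a (6, 2) array-like ordered p1..p6 with p1/p4 the
    horizontal eye corners, (p2, p6) and (p3, p5) the upper/lower lid
    pairs. Scale- and translation-invariant.
    """
    p = np.asarray(landmarks, dtype=float)
    if p.shape != (6, 2):
        raise ValueError("landmarks must be a (6, 2) array of points p1..p6")
    horizontal = float(np.linalg.norm(p[0] - p[3]))
    if horizontal <= 0.0 or not math.isfinite(horizontal):
        raise ValueError("degenerate eye: horizontal extent |p1 - p4| must be > 0")
    v1 = float(np.linalg.norm(p[1] - p[5]))
    v2 = float(np.linalg.norm(p[2] - p[4]))
    return (v1 + v2) / (2.0 * horizontal)


def compute_perclos(ears, valid=None) -> float:
    """PERCLOS of one window: closed-frame fraction among valid frames.

    ``ears`` holds the window's EAR values (at most the last 300 frames);
    ``valid`` optionally masks dropped frames. Closed means EAR strictly
    below 0.3. With no valid frame the value is undefined and NaN is
    returned (the unitization stage treats it as missing).
    """
    e = np.asarray(ears, dtype=float)
    mask = np.isfinite(e) if valid is None else (np.asarray(valid, dtype=bool) & np.isfinite(e))
    n_valid = int(mask.sum())
    if n_valid == 0:
        return float("nan")
    return float((e[mask] < EAR_CLOSURE_THRESHOLD).sum()) / n_valid


def fuse_m(ear: float, perclos: float) -> float:
    """Fused ocular metric M = 0.3*EAR + 0.7*PERCLOS."""
    if not (math.isfinite(ear) and math.isfinite(perclos)) or ear < 0 or perclos < 0:
        raise ValueError("ear and perclos must be finite and nonnegative")
    return M_EAR_WEIGHT * ear + M_PERCLOS_WEIGHT * perclos


def classify_fatigue_level(n_consecutive: int) -> FatigueLevel:
    """Grade a run of N consecutive frames with M > 0.605."""
    n = int(n_consecutive)
    if n < 0:
        raise ValueError("n_consecutive must be nonnegative")
    if n <= 5:
        return FatigueLevel.NONE
    if n <= 15:
        return FatigueLevel.MILD
    if n < ALARM_RUN_LENGTH:
        return FatigueLevel.MODERATE
    return FatigueLevel.SEVERE


@dataclass
class FatigueEvent:
    """One logged engine event (run termination or alarm transition)."""

    timestamp_s: float
    frame_index: int
    kind: str  # "occurrence" | "alarm_on" | "alarm_off"
    level: FatigueLevel = FatigueLevel.NONE
    run_length: int = 0


@dataclass
class FatigueState:
    """Streaming fatigue state machine over one subject's frame stream."""

    fps: float = 30.0
    window: deque = field(default_factory=lambda: deque(maxlen=PERCLOS_WINDOW))
    n_consecutive: int = 0
    perclos: float = float("nan")
    m: float = float("nan")
    occurrence_counts: dict = field(
        default_factory=lambda: {
            FatigueLevel.MILD: 0,
            FatigueLevel.MODERATE: 0,
            FatigueLevel.SEVERE: 0,
        }
    )
    alarm_active: bool = False
    event_log: list = field(default_factory=list)
    _n_valid_in_window: int = 0
    _n_closed_in_window: int = 0
    _consecutive_invalid: int = 0
    _last_frame_index: int = -1

    def _close_run(self, frame_index: int) -> None:
        if self.n_consecutive == 0:
            return
        ts = frame_index / self.fps
        level = classify_fatigue_level(self.n_consecutive)
        if level >= FatigueLevel.MILD:
            self.occurrence_counts[level] += 1
            self.event_log.append(
                FatigueEvent(ts, frame_index, "occurrence", level, self.n_consecutive)
            )
        self.n_consecutive = 0
        if self.alarm_active:
            self.alarm_active = False
            self.event_log.append(FatigueEvent(ts, frame_index, "alarm_off"))

    def step(self, ear: float, valid: bool, frame_index: int) -> None:
        """Consume one frame. Frames must arrive in strictly increasing order."""
        frame_index = int(frame_index)
        if frame_index <= self._last_frame_index:
            raise ValueError(
                f"out-of-order frame index {frame_index} after {self._last_frame_index}"
            )
        self._last_frame_index = frame_index

        valid = bool(valid) and ear is not None and math.isfinite(ear)
        if len(self.window) == self.window.maxlen:
            old_ear, old_valid = self.window[0]
            if old_valid:
                self._n_valid_in_window -= 1
                if old_ear < EAR_CLOSURE_THRESHOLD:
                    self._n_closed_in_window -= 1
        self.window.append((ear if valid else float("nan"), valid))
        if valid:
            self._n_valid_in_window += 1
            if ear < EAR_CLOSURE_THRESHOLD:
                self._n_closed_in_window += 1

        self.perclos = (
            self._n_closed_in_window / self._n_valid_in_window
            if self._n_valid_in_window
            else float("nan")
        )

        if valid:
            self._consecutive_invalid = 0
            self.m = fuse_m(ear, self.perclos)
            above = self.m > M_RUN_THRESHOLD
        else:
            self._consecutive_invalid += 1
            if self._consecutive_invalid > MAX_CARRIED_INVALID:
                above = False  # too many dropped frames: the run closes
            else:
                above = math.isfinite(self.m) and self.m > M_RUN_THRESHOLD

        if above:
            self.n_consecutive += 1
            if self.n_consecutive >= ALARM_RUN_LENGTH and not self.alarm_active:
                self.alarm_active = True
                self.event_log.append(
                    FatigueEvent(frame_index / self.fps, frame_index, "alarm_on")
                )
        else:
            self._close_run(frame_index)

    def finalize(self) -> None:
        """Close any open run at stream end (attributed to the last frame)."""
        if self.n_consecutive > 0:
            self._close_run(max(self._last_frame_index, 0))


def step_fatigue_state(state: FatigueState, frame) -> FatigueState:
    """Advance ``state`` by one frame record (mutates and returns it).

    ``frame`` is any object or mapping with ``ear``, ``valid`` and
    ``frame_index`` fields.
    """
    get = frame.get if isinstance(frame, dict) else lambda k: getattr(frame, k)
    state.step(get("ear"), get("valid"), get("frame_index"))
    return state


def process_stream(frames: pd.DataFrame, fps: float = 30.0) -> tuple[pd.DataFrame, FatigueState]:
    """Run the engine over a whole frame table.

    Returns the timestamped per-frame log (``timestamp_s, ear, perclos,
    m, n_consecutive, level_event, alarm``) mirroring the monitoring
    system's session CSV, together with the final :class:`FatigueState`
    (occurrence counters and event log included).
    """
    state = FatigueState(fps=fps)
    n = len(frames)
    perclos = np.empty(n)
    m = np.empty(n)
    n_consec = np.empty(n, dtype=np.int64)
    alarm = np.empty(n, dtype=bool)
    level_event = np.zeros(n, dtype=np.int8)

    ears = frames["ear"].to_numpy(dtype=float)
    valids = frames["valid"].to_numpy(dtype=bool)
    indices = frames["frame_index"].to_numpy(dtype=np.int64)
    for i in range(n):
        events_before = len(state.event_log)
        state.step(ears[i], valids[i], indices[i])
        perclos[i] = state.perclos
        m[i] = state.m
        n_consec[i] = state.n_consecutive
        alarm[i] = state.alarm_active
        for ev in state.event_log[events_before:]:
            if ev.kind == "occurrence":
                level_event[i] = int(ev.level)
    state.finalize()
    log = pd.DataFrame(
        {
            "frame_index": indices,
            "timestamp_s": indices / fps,
            "ear": ears,
            "valid": valids,
            "perclos": perclos,
            "m": m,
            "n_consecutive": n_consec,
            "level_event": level_event,
            "alarm": alarm,
        }
    )
    return log, state
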