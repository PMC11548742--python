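"""Canonical per-minute indicator registry.

The minute-level sample carries three families of physiological
indicators — real-time fatigue metrics derived from the camera stream,
eye-movement metrics from the eye tracker, and respiration metrics from
the chest band. The area-of-interest (AOI) gaze percentage is stored as
two columns, one per screen region (AOI0: the ramp-simulation display,
AOI1: the fatigue-monitor display).

Two distinct gaze-duration averages are carried (``gaze_duration_avg``
and ``gaze_duration_avg_alt``); the protocols that produce them differ
only in the tracker's export and both are kept under disambiguated
names.
"""

from __future__ import annotations

#: Frame-derived fatigue metrics; always survive variance prescreening.
FATIGUE_COLUMNS: list[str] = [
    "ear_avg",
    "perclos_avg",
    "m_avg",
    "mild_occurrences",
    "moderate_occurrences",
    "severe_occurrences",
]

#: Eye-tracker metrics.
EYE_COLUMNS: list[str] = [
    "pupil_diameter_avg",        # mm
    "blink_count",               # blinks/minute
    "gaze_duration_avg",         # ms
    "sweep_length_avg",          # px
    "gaze_point_count",
    "sweep_count",
    "gaze_duration_avg_alt",     # ms
    "sweep_duration_avg",        # ms
    "aoi_gaze_duration_avg",     # ms
    "pct_gaze_aoi0",             # fraction of minute in AOI0
    "pct_gaze_aoi1",             # fraction of minute in AOI1
    "aoi_transfer_count",        # gaze transfers AOI0 <-> AOI1
    "aoi_non_aoi_transfer_count",  # gaze transfers AOI <-> elsewhere
]

#: Respiration metrics.
RESP_COLUMNS: list[str] = [
    "respiratory_rate",          # breaths/minute
    "respiratory_amplitude_avg",
]

#: All minute-level indicators, in canonical order.
INDICATOR_COLUMNS: list[str] = FATIGUE_COLUMNS + EYE_COLUMNS + RESP_COLUMNS

#: Indicators generated by the synthetic eye tracker / respiration band
#: (everything that is not derived from the camera frame stream).
SENSOR_COLUMNS: list[str] = EYE_COLUMNS + RESP_COLUMNS

#: Fraction-valued indicators, constrained to [0, 1].
FRACTION_COLUMNS: list[str] = ["perclos_avg", "m_avg", "pct_gaze_aoi0", "pct_gaze_aoi1"]

#: Count-valued indicators, constrained to nonnegative integers.
COUNT_COLUMNS: list[str] = [
    "mild_occurrences",
    "moderate_occurrences",
    "severe_occurrences",
    "blink_count",
    "gaze_point_count",
    "sweep_count",
    "aoi_transfer_count",
    "aoi_non_aoi_transfer_count",
]

#: Name of the within-session time feature (1-based minute index).
TIME_COLUMN: str = "minute"
SUBJECT_COLUMN: str = "subject_id"
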