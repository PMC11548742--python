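import numpy as np
import pandas as pd
import pytest

from rampload import synthetic


@pytest.fixture(scope="session")
def small_config():
    """Two subjects, six minutes: fast but long enough for fatigue runs."""
    return synthetic.SimConfig(
        n_subjects=2,
        duration_min=6,
        fatigue_episode_rate=(0.5, 1.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    streams, minute_table = synthetic.simulate_cohort(small_config)
    return streams, minute_table


def make_frame_df(ears, valid=None, subject_id="S01", fps=30):
    """Frame table from a raw EAR sequence (helper for engine tests)."""
    ears = np.asarray(ears, dtype=float)
    n = len(ears)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    idx = np.arange(n)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "frame_index": idx,
            "timestamp_s": idx / fps,
            "ear": np.where(valid, ears, np.nan),
            "valid": np.asarray(valid, dtype=bool),
        }
    )
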