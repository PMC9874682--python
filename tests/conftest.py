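import numpy as np
import pandas as pd
import pytest

from gazedyn.config import SimulationConfig
from gazedyn.simulate import simulate_dataset


def make_trial(word_durations, x_char=None, events=None):
    """Build a fixation table from (word_index, duration) pairs."""
    n = len(word_durations)
    df = pd.DataFrame({
        "participant_id": ["p1"] * n,
        "sentence_id": ["s1"] * n,
        "fixation_index": np.arange(1, n + 1),
        "word_index": [w for w, _ in word_durations],
        "duration_ms": [d for _, d in word_durations],
        "event": events if events is not None else ["fixation"] * n,
    })
    if x_char is not None:
        df["word_index"] = np.nan
        df["x_char"] = x_char
    return df


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-reader, 15-sentence experiment reused by read-only tests."""
    cfg = SimulationConfig(n_participants=10, n_sentences=15, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    from gazedyn.gaze import extract_measures

    return extract_measures(small_dataset.fixations, small_dataset.stimuli,
                            skip_filter={"max_length": 3,
                                         "min_log_frequency": 12.0})
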