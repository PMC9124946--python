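import numpy as np
import pandas as pd
import pytest

from fairgame.synthetic import CohortSpec, iter_participants


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """Small but complete cohort: both games, EEG, 80-trial sessions."""
    return CohortSpec(group_sizes={"GrpS": 3, "GrpB": 4, "GrpF": 4},
                      seed=123, n_blocks=2, block_size=40)


@pytest.fixture(scope="session")
def behavioral_cohort():
    """Behavior-only cohort at full session length (no EEG, fast)."""
    spec = CohortSpec(group_sizes={"GrpS": 8, "GrpB": 10, "GrpF": 10},
                      seed=7, eeg_games=())
    frames = [b for _, _, b, _, _ in iter_participants(spec)]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
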