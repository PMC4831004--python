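import numpy as np
import pandas as pd
import pytest

from ernlab.config import CohortConfig
from ernlab.containers import EpochSet
from ernlab.montage import load_montage


@pytest.fixture(scope="session")
def montage60():
    return load_montage("standard-60")


@pytest.fixture(scope="session")
def montage32():
    return load_montage("standard-32")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trials(rts, accs, subject_id="s001", sex="female", age=25.0,
                congruency=None, multi=None):
    """Minimal single-subject trial table for behavioural toys."""
    n = len(rts)
    r = np.random.default_rng(n)  # deterministic for a given length
    cong = congruency if congruency is not None \
        else list(r.choice(["congruent", "incongruent"], n))
    rsi = list(r.choice(["short", "long"], n))
    return pd.DataFrame({
        "subject_id": subject_id,
        "sex": sex,
        "age": age,
        "trial_index": np.arange(1, n + 1),
        "congruency": cong,
        "distance": list(r.choice(["close", "far"], n)),
        "rsi": rsi,
        "next_rsi": rsi[1:] + [None],
        "response_hand": list(r.choice(["left", "right"], n)),
        "accuracy": accs,
        "rt": np.asarray(rts, dtype=float),
        "multi_response": multi if multi is not None else [False] * n,
    })


def make_epochs(data, times=None, labels=None, subject_id="s001",
                sampling_rate=500.0):
    data = np.asarray(data)
    n, e, t = data.shape
    if times is None:
        times = np.arange(t) * 2.0 - 100.0
    if labels is None:
        labels = [f"ch{i}" for i in range(e)]
    return EpochSet(data=data, times=np.asarray(times, dtype=float),
                    electrode_labels=list(labels), subject_id=subject_id,
                    trial_link=np.arange(n), sampling_rate=sampling_rate)


@pytest.fixture
def toy_sequence_cfg():
    return CohortConfig(n_female=1, n_male=1, n_trials=80)
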