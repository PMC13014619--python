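from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from tapcog.events import TapEvent, TrialRecord, VerbalAttempt, VerbalPair
from tapcog.simulate import LatentProfile


@pytest.fixture
def healthy_profile() -> LatentProfile:
    return LatentProfile(
        motor_floor=0.30,
        motor_jitter=3.0,
        cog_latency_scale=0.55,
        memory_capacity=7.0,
        lapse_rate=0.03,
        self_correct_prob=0.35,
    )


@pytest.fixture
def impaired_profile() -> LatentProfile:
    return LatentProfile(
        motor_floor=0.60,
        motor_jitter=2.0,
        cog_latency_scale=1.3,
        memory_capacity=4.5,
        lapse_rate=0.12,
        self_correct_prob=0.35,
    )


def make_verbal_trial(
    n_correct: int = 10,
    stage: str = "verbal_immediate",
    times_ms=None,
    subject_id: str = "fixture",
) -> TrialRecord:
    """One-attempt verbal trial with the given number of correct answers."""
    if times_ms is None:
        times_ms = [1000 * (i + 1) for i in range(10)]
    pairs = []
    for j in range(10):
        options = tuple(f"w{j}_{k}" for k in range(4))
        correct = j < n_correct
        chosen = options[0] if correct else options[1]
        pairs.append(
            VerbalPair(
                cue=f"cue{j}",
                options=options,
                chosen=chosen,
                event=TapEvent(times_ms[j], "select", options.index(chosen), correct),
            )
        )
    return TrialRecord(
        subject_id=subject_id,
        stage=stage,
        session_time=datetime(2023, 1, 2, 9, 0),
        attempts=(VerbalAttempt(pairs=tuple(pairs)),),
    )


def longitudinal_scores(n_subjects, n_visits, var_between, var_within, seed):
    """Long-format repeated scores from a random-intercept model."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(var_between), n_subjects)
    rows = {
        "subject_id": np.repeat([f"s{i:03d}" for i in range(n_subjects)], n_visits),
        "score": np.repeat(u, n_visits) + rng.normal(0.0, np.sqrt(var_within), n_subjects * n_visits),
    }
    return pd.DataFrame(rows)
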