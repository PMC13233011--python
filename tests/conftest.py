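from datetime import datetime, timedelta

import numpy as np
import pytest

import dosewise as dw


def make_glucose_stream(values, start=datetime(2021, 7, 1, 9, 0), step_min=5,
                        extra_events=(), patient_id="p1"):
    """Stream of 5-min glucose readings plus any extra events."""
    events = [
        dw.RawEvent("glucose", start + timedelta(minutes=i * step_min), float(v))
        for i, v in enumerate(values) if v is not None
    ]
    events.extend(extra_events)
    return dw.EventStream(patient_id=patient_id, cohort="2018", events=events)


@pytest.fixture(scope="session")
def patient_timeline():
    """Two preprocessed weeks of one synthetic patient."""
    stream = dw.generate_patient(weeks=2, seed=7)
    return dw.preprocess(stream)


@pytest.fixture(scope="session")
def env_factory():
    return dw.make_env_factory()


@pytest.fixture(scope="session")
def short_env_factory():
    """One-day episodes; keeps rollout-heavy tests quick."""
    from dataclasses import replace

    cfg = replace(dw.EnvConfig(), episode_len=288)
    return dw.make_env_factory(cfg)


@pytest.fixture(scope="session")
def trained_policy(env_factory):
    policy, curve = dw.train(env_factory, dw.TrainConfig(episodes=10, seed=1))
    return policy


def random_states(n, rng):
    states = []
    for _ in range(n):
        states.append(dw.EnvState(
            glucose_window=rng.uniform(40, 400, 24),
            insulin_window=rng.uniform(0, 5, 24),
            carb_window=rng.uniform(0, 100, 24),
            exercise_window=rng.integers(0, 6, 24).astype(float),
            time_since_last_meal=float(rng.uniform(0, 720)),
            time_since_last_dose=float(rng.uniform(0, 720)),
            hour_of_day=int(rng.integers(0, 24)),
            iob=float(rng.uniform(0, 10)),
        ))
    return states
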