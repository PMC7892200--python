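import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import fpl
from fpl.cohort import FormantTrack
from fpl.dataio import Dataset
from fpl.design import ScheduleConfig


def small_schedule_config(seed: int, **kw) -> ScheduleConfig:
    """A structurally complete but miniature five-session design."""
    defaults = dict(rng_seed=seed, head_per_condition=3, hid_per_condition=1,
                    unperturbed_head=4, unperturbed_hid=2,
                    n_familiarization=3, baseline_counts=(4, 2),
                    hold_counts=(6, 2), washout_counts=(4, 2))
    defaults.update(kw)
    return ScheduleConfig(**defaults)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free three-participant cohort, all five sessions."""
    return fpl.simulate_cohort(fpl.preset("clean", rng_seed=7,
                                          n_participants=3))


@pytest.fixture(scope="session")
def clean_dataset(clean_cohort):
    return fpl.from_cohort(clean_cohort)


@pytest.fixture(scope="session")
def tiny_realistic_cohort():
    """Small realistic cohort with the miniature schedule (fast IO tests)."""
    cfg = fpl.preset("realistic", rng_seed=11, n_participants=2,
                     schedule=small_schedule_config(11))
    return fpl.simulate_cohort(cfg)


def make_dataset(tracks: dict, schedule_rows: list[dict],
                 participants: list[str] | None = None) -> Dataset:
    """Assemble a hand-built Dataset from track objects and schedule rows."""
    sched = pd.DataFrame(schedule_rows)
    if participants is None:
        participants = sorted(sched.participant_id.unique())
    pdf = pd.DataFrame({"participant_id": participants,
                        "group": ["plus_first"] * len(participants),
                        "age": [25.0] * len(participants)})
    return Dataset(sched, tracks, pdf)


def flat_track(pid: str, session: int, trial: int, f1: np.ndarray,
               dt: float = 3.0, flag: str = "good") -> FormantTrack:
    return FormantTrack(pid, session, trial, dt, np.asarray(f1, float),
                        quality_flag=flag)


def schedule_row(pid: str, session: int, trial: int, word: str = "head",
                 phase: str = "unpredictable", kind: str = "none",
                 hz: float = 0.0, onset: float = 0.0,
                 duration: float = 0.0) -> dict:
    return {"participant_id": pid, "session": session, "trial_index": trial,
            "word": word, "phase": phase, "pert_kind": kind, "pert_hz": hz,
            "pert_onset_ms": onset, "pert_duration_ms": duration,
            "rng_seed": 0}
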