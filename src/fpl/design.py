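"""Trial schedules for formant-feedback perturbation experiments.

The experiment comprises five sessions of 165 trials. Sessions 1, 3 and 5
probe online (within-trial) compensation with *unpredictable* F1 feedback
perturbations: eight conditions crossing perturbation timing (transient
mid-utterance vs. whole-utterance from voice onset) with four signed
magnitudes (-200, -50, +50, +200 Hz), interleaved with unperturbed trials
and infrequent "hid" catch trials. Sessions 2 and 4 probe sensorimotor
adaptation with a *consistent* whole-utterance +/-200 Hz perturbation over a
baseline / hold / washout phase structure, direction counterbalanced across
participants.

Schedules are pure functions of ``(rng_seed, participant_id,
counterbalance_group)``: the same inputs always yield the same trial
sequence.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Perturbation kinds
NONE = "none"
MID = "mid_utterance"
WHOLE = "whole_utterance"

MAGNITUDES_HZ = (-200.0, -50.0, 50.0, 200.0)
WORDS = ("head", "hid")

#: the eight unpredictable perturbation conditions (kind, magnitude)
CONDITIONS = tuple((kind, mag) for kind in (MID, WHOLE) for mag in MAGNITUDES_HZ)

SCHEDULE_COLUMNS = [
    "participant_id", "session", "trial_index", "word", "phase",
    "pert_kind", "pert_hz", "pert_onset_ms", "pert_duration_ms", "rng_seed",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """One feedback perturbation: kind, signed magnitude, onset and duration.

    ``kind`` is one of ``"none"``, ``"mid_utterance"`` (transient, 400 ms,
    jittered 200-500 ms onset delay from voice onset) or
    ``"whole_utterance"`` (from voice onset for the full utterance;
    ``duration_ms`` is ``inf``).
    """

    kind: str
    magnitude_hz: float
    onset_delay_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.kind not in (NONE, MID, WHOLE):
            raise ValueError(f"unknown perturbation kind: {self.kind!r}")
        if (self.kind == NONE) != (self.magnitude_hz == 0):
            raise ValueError("kind='none' if and only if magnitude is 0 Hz")
        if self.kind == MID:
            if not (200.0 <= self.onset_delay_ms <= 500.0):
                raise ValueError("mid-utterance onset delay outside [200, 500] ms")
            if self.duration_ms != 400.0:
                raise ValueError("mid-utterance perturbations last 400 ms")
        if self.kind == WHOLE and self.onset_delay_ms != 0.0:
            raise ValueError("whole-utterance perturbations start at voice onset")

    @property
    def offset_ms(self) -> float:
        """Perturbation end time (ms from voice onset); inf for whole-utterance."""
        return self.onset_delay_ms + self.duration_ms


UNPERTURBED = PerturbationSpec(NONE, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TrialSpec:
    participant_id: str
    session: int
    trial_index: int  # 1-based within session
    word: str
    phase: str  # familiarization | unpredictable | baseline | hold | washout
    perturbation: PerturbationSpec


@dataclass(frozen=True)
class ScheduleConfig:
    """Knobs of the five-session design.

    Default counts reproduce the published design exactly: per unpredictable
    condition 45 "head" + 9 "hid" trials (8 x 54 = 432 perturbed), 30 + 18
    unperturbed, 15 familiarization trials; adaptation sessions 42/81/42
    baseline/hold/washout with 30/60/30 "head" trials.
    """

    rng_seed: int = 0
    counterbalance_group: str = "plus_first"  # or "minus_first"
    jitter_ms: tuple[float, float] = (200.0, 500.0)
    head_per_condition: int = 45
    hid_per_condition: int = 9
    unperturbed_head: int = 30
    unperturbed_hid: int = 18
    n_familiarization: int = 15
    mid_duration_ms: float = 400.0
    adapt_magnitude_hz: float = 200.0
    baseline_counts: tuple[int, int] = (30, 12)   # (head, hid)
    hold_counts: tuple[int, int] = (60, 21)
    washout_counts: tuple[int, int] = (30, 12)
    magnitudes_hz: tuple[float, ...] = MAGNITUDES_HZ

    def __post_init__(self) -> None:
        if self.counterbalance_group not in ("plus_first", "minus_first"):
            raise ValueError(
                f"unknown counterbalance group: {self.counterbalance_group!r}")
        lo, hi = self.jitter_ms
        if not (lo <= hi):
            raise ValueError("jitter bounds must satisfy lo <= hi")

    def hold_magnitude(self, session: int) -> float:
        """Signed hold-phase perturbation for adaptation session 2 or 4."""
        if session not in (2, 4):
            raise ValueError(f"adaptation sessions are 2 and 4, got {session}")
        plus_session = 2 if self.counterbalance_group == "plus_first" else 4
        sign = 1.0 if session == plus_session else -1.0
        return sign * self.adapt_magnitude_hz


def _participant_rng(config: ScheduleConfig, participant_id: str,
                     stream: int) -> np.random.Generator:
    # stable per-participant stream derived from the schedule seed
    tag = zlib.crc32(str(participant_id).encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed), tag, stream]))


def _make_pert(config: ScheduleConfig, kind: str, mag: float,
               rng: np.random.Generator) -> PerturbationSpec:
    if kind == NONE:
        return UNPERTURBED
    if kind == MID:
        lo, hi = config.jitter_ms
        onset = float(rng.uniform(lo, hi))
        return PerturbationSpec(MID, mag, onset, config.mid_duration_ms)
    return PerturbationSpec(WHOLE, mag, 0.0, math.inf)


def build_unpredictable_sessions(config: ScheduleConfig,
                                 participant_id: str) -> list[TrialSpec]:
    """Schedule sessions 1, 3, 5 (495 trials; 165 per session).

    Session 1 opens with the familiarization trials (sampled uniformly over
    the 10 trial types); the 480-trial main pool (432 perturbed over 8
    conditions + 48 unperturbed) is shuffled once and split 150/165/165
    across the three sessions.
    """
    rng = _participant_rng(config, participant_id, stream=1)
    conditions = tuple((kind, mag) for kind in (MID, WHOLE)
                       for mag in config.magnitudes_hz)

    pool: list[tuple[str, str, float]] = []
    for kind, mag in conditions:
        pool += [("head", kind, mag)] * config.head_per_condition
        pool += [("hid", kind, mag)] * config.hid_per_condition
    pool += [("head", NONE, 0.0)] * config.unperturbed_head
    pool += [("hid", NONE, 0.0)] * config.unperturbed_hid
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    trial_types = list(conditions) + [(NONE, 0.0)]
    fam: list[tuple[str, str, float]] = []
    for _ in range(config.n_familiarization):
        word = WORDS[int(rng.integers(2))]
        kind, mag = trial_types[int(rng.integers(len(trial_types)))]
        fam.append((word, kind, mag))

    n_main = len(pool)
    per_session = (len(fam) + n_main) // 3
    n1 = per_session - len(fam)
    n_rest = (n_main - n1) // 2
    splits = {1: pool[:n1], 3: pool[n1:n1 + n_rest], 5: pool[n1 + n_rest:]}

    trials: list[TrialSpec] = []
    for session in (1, 3, 5):
        idx = 1
        if session == 1:
            for word, kind, mag in fam:
                trials.append(TrialSpec(participant_id, session, idx, word,
                                        "familiarization",
                                        _make_pert(config, kind, mag, rng)))
                idx += 1
        for word, kind, mag in splits[session]:
            trials.append(TrialSpec(participant_id, session, idx, word,
                                    "unpredictable",
                                    _make_pert(config, kind, mag, rng)))
            idx += 1
    return trials


def build_adaptation_session(config: ScheduleConfig, participant_id: str,
                             session: int) -> list[TrialSpec]:
    """Schedule one adaptation session (2 or 4): baseline / hold / washout.

    Hold-phase trials all carry the session's single whole-utterance
    perturbation (+200 or -200 Hz by counterbalance group); baseline and
    washout trials are unperturbed. Word order is shuffled within each phase.
    """
    mag = config.hold_magnitude(session)  # validates session
    rng = _participant_rng(config, participant_id, stream=session)
    hold_pert = PerturbationSpec(WHOLE, mag, 0.0, math.inf)

    trials: list[TrialSpec] = []
    idx = 1
    for phase, (n_head, n_hid), pert in (
            ("baseline", config.baseline_counts, UNPERTURBED),
            ("hold", config.hold_counts, hold_pert),
            ("washout", config.washout_counts, UNPERTURBED)):
        words = ["head"] * n_head + ["hid"] * n_hid
        order = rng.permutation(len(words))
        for i in order:
            trials.append(TrialSpec(participant_id, session, idx, words[i],
                                    phase, pert))
            idx += 1
    return trials


def build_full_schedule(config: ScheduleConfig,
                        participant_id: str) -> list[TrialSpec]:
    """All five sessions for one participant, in session order."""
    trials = build_unpredictable_sessions(config, participant_id)
    trials += build_adaptation_session(config, participant_id, 2)
    trials += build_adaptation_session(config, participant_id, 4)
    trials.sort(key=lambda t: (t.session, t.trial_index))
    return trials


def head_trial_ordinals(schedule: list[TrialSpec]) -> dict[int, int]:
    """Map trial_index -> 1-based ordinal among "head" trials of one session.

    Catch ("hid") trials are skipped; analysis windows such as "head trials
    76-90" index into this numbering.
    """
    ordinals: dict[int, int] = {}
    k = 0
    for t in sorted(schedule, key=lambda t: t.trial_index):
        if t.word == "head":
            k += 1
            ordinals[t.trial_index] = k
    return ordinals


# ---------------------------------------------------------------- CSV I/O

def schedule_to_frame(trials: list[TrialSpec],
                      rng_seed: int | None = None) -> pd.DataFrame:
    rows = [{
        "participant_id": t.participant_id,
        "session": t.session,
        "trial_index": t.trial_index,
        "word": t.word,
        "phase": t.phase,
        "pert_kind": t.perturbation.kind,
        "pert_hz": t.perturbation.magnitude_hz,
        "pert_onset_ms": t.perturbation.onset_delay_ms,
        "pert_duration_ms": t.perturbation.duration_ms,
        "rng_seed": rng_seed,
    } for t in trials]
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def frame_to_schedule(df: pd.DataFrame) -> list[TrialSpec]:
    trials = []
    for row in df.itertuples(index=False):
        pert = PerturbationSpec(row.pert_kind, float(row.pert_hz),
                                float(row.pert_onset_ms),
                                float(row.pert_duration_ms))
        trials.append(TrialSpec(str(row.participant_id), int(row.session),
                                int(row.trial_index), row.word, row.phase,
                                pert))
    return trials


def write_schedule_csv(trials: list[TrialSpec], path,
                       rng_seed: int | None = None) -> None:
    schedule_to_frame(trials, rng_seed).to_csv(path, index=False,
                                               float_format="%.17g")


def read_schedule_csv(path) -> list[TrialSpec]:
    df = pd.read_csv(path, float_precision="round_trip")
    return frame_to_schedule(df)
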