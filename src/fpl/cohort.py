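"""Synthetic cohort simulator: a feedback + feedforward control model of F1.

No raw recordings accompany the published design, so every analysis stage in
this package is validated against synthetic sustained-vowel F1 tracks with
known ground truth. The generative model for a single trial is

    f1(t) = f1_baseline + trend_amplitude * exp(-t / trend_tau)
            + s + c(t) + eps_trial + eps_frame(t)

with ``t`` in ms from voice onset, ``s`` the current feedforward adaptation
state (Hz), ``c(t)`` the within-trial feedback compensation, and Gaussian
trial-level / frame-level noise. For a perturbation of signed magnitude
``p`` Hz starting at ``t_p``, the compensation opposes the perturbation with
gain ``g``, latency ``L`` and first-order time constant ``tau_c``:

    c(t) = 0                                             t <  t_p + L
    c(t) = -g * p * (1 - exp(-(t - t_p - L) / tau_c))    during perturbation
    c(t) -> 0 with time constant tau_c after a transient perturbation ends
            (the offset is sensed with the same latency L)

Across trials of an adaptation session the feedforward state follows a
single-rate learning rule with retention ``r`` and learning rate ``beta``:

    s[k+1] = r * s[k] - beta * p[k],     s[1] = 0

so a constant perturbation drives the state to the plateau
``s_inf = -beta * p / (1 - r)``, i.e. an asymptotic adaptation of
``100 * beta / (1 - r)`` percent of the perturbation.

Cohort-level draws can couple the mid- and whole-utterance compensation
gains (``rho_mid_whole``) and the compensation gain with the adaptation
rate (``rho_comp_adapt``); both knobs exist so analyses that test for such
correlations can be exercised against cohorts where the answer is known.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (MID, NONE, WHOLE, ScheduleConfig, TrialSpec,
                     build_adaptation_session, build_unpredictable_sessions)

GROUND_TRUTH_COLUMNS = [
    "participant_id", "group", "age", "f1_baseline", "trend_amplitude",
    "trend_tau", "g_mid", "g_whole", "g_boost_mid", "g_boost_whole",
    "comp_latency", "comp_tau", "adapt_rate", "adapt_retention",
    "plateau_pct", "noise_frame", "noise_trial",
]

#: perturbations at or below this magnitude get the small-perturbation
#: gain boost (percent compensation is empirically larger for 50 Hz than
#: for 200 Hz shifts)
SMALL_PERT_HZ = 100.0


@dataclass(frozen=True)
class ParticipantModel:
    """Parameters of one simulated speaker.

    Gains are fractions of the perturbation opposed (0.05 = 5 % asymptotic
    compensation); latencies and time constants are in ms; noise SDs in Hz.
    ``g_boost_mid`` / ``g_boost_whole`` multiply the gain for small
    (|p| <= 100 Hz) perturbations, reproducing the empirically larger
    *percent* compensation to 50 Hz than to 200 Hz shifts. ``adapt_rate``
    (beta) and ``adapt_retention`` (r) govern the across-trial feedforward
    state; ``age`` is carried only as a model covariate.
    """

    participant_id: str
    f1_baseline: float = 600.0
    trend_amplitude: float = 0.0
    trend_tau: float = 80.0
    g_mid: float = 0.0
    g_whole: float = 0.0
    g_boost_mid: float = 1.0
    g_boost_whole: float = 1.0
    comp_latency: float = 275.0
    comp_tau: float = 120.0
    adapt_rate: float = 0.0
    adapt_retention: float = 0.9
    noise_frame: float = 0.0
    noise_trial: float = 0.0
    age: float = 22.0

    def __post_init__(self) -> None:
        vals = [self.f1_baseline, self.trend_amplitude, self.trend_tau,
                self.g_mid, self.g_whole, self.g_boost_mid,
                self.g_boost_whole, self.comp_latency, self.comp_tau,
                self.adapt_rate, self.adapt_retention, self.noise_frame,
                self.noise_trial, self.age]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite participant parameter")
        if self.noise_frame < 0 or self.noise_trial < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0.0 <= self.adapt_retention < 1.0):
            raise ValueError("retention must lie in [0, 1)")
        if self.trend_tau <= 0 or self.comp_tau < 0:
            raise ValueError("time constants must be positive (comp_tau >= 0)")

    def gain_for(self, kind: str, magnitude_hz: float = 200.0) -> float:
        g = self.g_mid if kind == MID else self.g_whole
        if abs(magnitude_hz) <= SMALL_PERT_HZ:
            g *= self.g_boost_mid if kind == MID else self.g_boost_whole
        return g

    @property
    def plateau_pct(self) -> float:
        """Asymptotic adaptation, percent of a constant perturbation."""
        return 100.0 * self.adapt_rate / (1.0 - self.adapt_retention)


@dataclass
class FormantTrack:
    """One trial's F1 track on a uniform frame grid aligned at voice onset.

    Frame ``k`` is at time ``k * frame_interval_ms`` relative to voice
    onset (``voice_onset_frame`` is index 0 of ``f1``).
    """

    participant_id: str
    session: int
    trial_index: int
    frame_interval_ms: float
    f1: np.ndarray
    voice_onset_frame: int = 0
    voice_offset_frame: int | None = None
    quality_flag: str = "good"

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        if self.voice_offset_frame is None:
            self.voice_offset_frame = len(self.f1)

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(len(self.f1)) - self.voice_onset_frame) \
            * self.frame_interval_ms

    @property
    def duration_ms(self) -> float:
        return (self.voice_offset_frame - self.voice_onset_frame) \
            * self.frame_interval_ms

    def window_mean(self, start_ms: float, stop_ms: float) -> float:
        """Mean F1 over the half-open window [start_ms, stop_ms)."""
        t = self.times_ms
        m = (t >= start_ms) & (t < stop_ms)
        if not m.any():
            raise ValueError(f"track does not cover [{start_ms}, {stop_ms}) ms")
        return float(self.f1[m].mean())


def compensation_timecourse(t_ms: np.ndarray, pert, gain: float,
                            latency_ms: float, tau_ms: float) -> np.ndarray:
    """Closed-form within-trial compensation c(t) for one perturbation.

    ``tau_ms == 0`` gives an instantaneous step at ``onset + latency`` (and
    an instantaneous return after a transient ends).
    """
    c = np.zeros_like(t_ms, dtype=float)
    if pert.kind == NONE or gain == 0.0:
        return c
    t_on = pert.onset_delay_ms + latency_ms
    target = -gain * pert.magnitude_hz
    if tau_ms == 0.0:
        rise = (t_ms >= t_on).astype(float)
    else:
        rise = np.where(t_ms >= t_on,
                        1.0 - np.exp(-np.maximum(t_ms - t_on, 0.0) / tau_ms),
                        0.0)
    c = target * rise
    if math.isfinite(pert.duration_ms):
        t_off = pert.offset_ms + latency_ms
        after = t_ms >= t_off
        if after.any():
            if tau_ms == 0.0:
                c[after] = 0.0
            else:
                c_off = target * (1.0 - math.exp(-(t_off - t_on) / tau_ms))
                c[after] = c_off * np.exp(-(t_ms[after] - t_off) / tau_ms)
    return c


def simulate_trial(model: ParticipantModel, trial: TrialSpec,
                   adapt_state: float, rng: np.random.Generator,
                   duration_ms: float = 2000.0,
                   frame_interval_ms: float = 3.0) -> FormantTrack:
    """Generate one trial's F1 track from the control model."""
    if duration_ms < 1000.0:
        raise ValueError("trial duration must be at least 1 s")
    if not math.isfinite(adapt_state):
        raise ValueError("non-finite adaptation state")
    n = int(duration_ms // frame_interval_ms)
    t = np.arange(n) * frame_interval_ms
    f1 = np.full(n, model.f1_baseline + adapt_state, dtype=float)
    if model.trend_amplitude != 0.0:
        f1 += model.trend_amplitude * np.exp(-t / model.trend_tau)
    f1 += compensation_timecourse(
        t, trial.perturbation,
        model.gain_for(trial.perturbation.kind,
                       trial.perturbation.magnitude_hz),
        model.comp_latency, model.comp_tau)
    if model.noise_trial > 0:
        f1 += rng.normal(0.0, model.noise_trial)
    if model.noise_frame > 0:
        f1 += rng.normal(0.0, model.noise_frame, size=n)
    return FormantTrack(trial.participant_id, trial.session,
                        trial.trial_index, frame_interval_ms, f1)


def simulate_adaptation_session(model: ParticipantModel,
                                schedule: list[TrialSpec],
                                rng: np.random.Generator,
                                duration_ms: float = 2000.0,
                                frame_interval_ms: float = 3.0,
                                ) -> tuple[list[FormantTrack], list[float]]:
    """Simulate one adaptation session, updating the feedforward state.

    Returns the tracks and the true state ``s_k`` in effect on each trial
    (the state updates after every trial, catch trials included, since the
    perturbation is applied on all hold-phase trials).
    """
    phases = {t.phase for t in schedule}
    if not phases <= {"baseline", "hold", "washout"}:
        raise ValueError(f"not an adaptation-session schedule: phases {phases}")
    tracks: list[FormantTrack] = []
    states: list[float] = []
    s = 0.0
    for trial in sorted(schedule, key=lambda t: t.trial_index):
        states.append(s)
        tracks.append(simulate_trial(model, trial, s, rng, duration_ms,
                                     frame_interval_ms))
        p = trial.perturbation.magnitude_hz
        s = model.adapt_retention * s - model.adapt_rate * p
    return tracks, states


def simulate_unpredictable_sessions(model: ParticipantModel,
                                    schedule: list[TrialSpec],
                                    rng: np.random.Generator,
                                    duration_ms: float = 2000.0,
                                    frame_interval_ms: float = 3.0,
                                    ) -> list[FormantTrack]:
    # unpredictable, sign-balanced perturbations: no net feedforward learning
    return [simulate_trial(model, t, 0.0, rng, duration_ms, frame_interval_ms)
            for t in sorted(schedule, key=lambda t: (t.session, t.trial_index))]


# ------------------------------------------------------------- cohorts

@dataclass(frozen=True)
class CohortConfig:
    """Population-level description of a simulated cohort.

    ``means`` / ``sds`` give the population distribution of each
    :class:`ParticipantModel` field (independent normals except for the
    correlated triple ``g_mid`` / ``g_whole`` / ``adapt_rate``).
    ``rho_mid_whole`` couples the two compensation gains across
    participants; ``rho_comp_adapt`` couples both gains with the adaptation
    rate.
    """

    n_participants: int = 22
    rng_seed: int = 0
    rho_mid_whole: float = 0.8
    rho_comp_adapt: float = 0.0
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    age_range: tuple[float, float] = (18.0, 43.0)
    clip_gains: bool = False
    p_exclude: float = 0.0
    frame_interval_ms: float = 3.0
    trial_duration_ms: float = 2000.0
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)

    def __post_init__(self) -> None:
        for rho in (self.rho_mid_whole, self.rho_comp_adapt):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlation parameters must lie in [-1, 1]")
        if not (0.0 <= self.p_exclude < 1.0):
            raise ValueError("exclusion probability must lie in [0, 1)")
        cov = self.gain_correlation()
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ValueError("implied gain/rate correlation matrix is not PSD")

    def gain_correlation(self) -> np.ndarray:
        """Correlation matrix of (g_mid, g_whole, adapt_rate)."""
        mw, ca = self.rho_mid_whole, self.rho_comp_adapt
        return np.array([[1.0, mw, ca],
                         [mw, 1.0, ca],
                         [ca, ca, 1.0]])


#: population parameters emulating the published cohort: baseline F1 around
#: 600 Hz, compensation gains a few percent (larger for whole-utterance),
#: latencies near 275 ms, adaptation plateau near 8-9 %, and noise levels
#: that put single-trial F1 SD near 13 Hz.
REALISTIC_MEANS = {
    "f1_baseline": 600.0, "trend_amplitude": 30.0, "trend_tau": 80.0,
    "g_mid": 0.03, "g_whole": 0.05, "g_boost_mid": 2.0, "g_boost_whole": 2.0,
    "comp_latency": 275.0, "comp_tau": 120.0,
    "adapt_rate": 0.0045, "adapt_retention": 0.95,
    "noise_frame": 6.0, "noise_trial": 12.0,
}
#: between-participant SDs; compensation-gain and adaptation-rate spreads
#: are calibrated so participant-level peak compensation and adaptation
#: percentages spread as widely as published group SEMs (x sqrt(n)) imply
#: (~3-5 % SD for +/-200 Hz compensation, ~11 % SD for adaptation), which
#: also makes a realistic minority of participants non-compensators or
#: non-adapters.
REALISTIC_SDS = {
    "f1_baseline": 50.0, "trend_amplitude": 10.0, "trend_tau": 15.0,
    "g_mid": 0.027, "g_whole": 0.045, "g_boost_mid": 0.5,
    "g_boost_whole": 0.5, "comp_latency": 30.0, "comp_tau": 25.0,
    "adapt_rate": 0.005, "adapt_retention": 0.015,
    "noise_frame": 1.0, "noise_trial": 3.0,
}

_PRESETS = {
    # the default study conditions: n=22, realistic noise, ~3 % of head
    # trials flagged excluded to exercise the screening path
    "realistic": dict(p_exclude=0.03),
    # same population but noise-free and without exclusions: closed-form
    # checks of the analysis pipeline
    "clean": dict(sds={k: 0.0 for k in REALISTIC_SDS},
                  means={**REALISTIC_MEANS, "noise_frame": 0.0,
                         "noise_trial": 0.0, "trend_amplitude": 30.0,
                         "g_boost_mid": 1.0, "g_boost_whole": 1.0},
                  p_exclude=0.0),
    # low noise, no exclusions, modest between-participant spread: recovery
    # tests where the measurement error should be negligible
    "high_snr": dict(means={**REALISTIC_MEANS, "noise_frame": 1.0,
                            "noise_trial": 1.5},
                     sds={**REALISTIC_SDS, "noise_frame": 0.0,
                          "noise_trial": 0.0, "comp_latency": 0.0},
                     p_exclude=0.0),
    # all compensation/adaptation gains clipped non-negative
    "compensator": dict(clip_gains=True, p_exclude=0.0),
}


def preset(name: str, rng_seed: int = 0, **overrides) -> CohortConfig:
    """Named cohort configurations ("realistic", "clean", "high_snr",
    "compensator")."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(means=dict(REALISTIC_MEANS), sds=dict(REALISTIC_SDS))
    kw.update({k: (dict(v) if isinstance(v, dict) else v)
               for k, v in _PRESETS[name].items()})
    kw.update(overrides)
    return CohortConfig(rng_seed=rng_seed, **kw)


def draw_cohort_models(config: CohortConfig,
                       ) -> tuple[list[ParticipantModel], pd.DataFrame]:
    """Draw participant parameter sets and the ground-truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))
    means = {**REALISTIC_MEANS, **config.means}
    sds = {**{k: 0.0 for k in REALISTIC_SDS}, **REALISTIC_SDS, **config.sds}
    corr = config.gain_correlation()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    mw = config.rho_mid_whole
    chol2 = np.linalg.cholesky(np.array([[1.0, mw], [mw, 1.0]])
                               + 1e-12 * np.eye(2))

    models, rows = [], []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        z = chol @ rng.standard_normal(3)
        params = {}
        for j, name in enumerate(("g_mid", "g_whole", "adapt_rate")):
            params[name] = means[name] + sds[name] * z[j]
        zb = chol2 @ rng.standard_normal(2)
        for j, name in enumerate(("g_boost_mid", "g_boost_whole")):
            params[name] = max(means[name] + sds[name] * zb[j], 0.0)
        for name in ("f1_baseline", "trend_amplitude", "trend_tau",
                     "comp_latency", "comp_tau", "adapt_retention",
                     "noise_frame", "noise_trial"):
            params[name] = means[name] + sds[name] * rng.standard_normal()
        if config.clip_gains:
            for name in ("g_mid", "g_whole", "adapt_rate"):
                params[name] = max(params[name], 0.0)
        # keep draws inside the model's validity ranges
        params["trend_tau"] = max(params["trend_tau"], 10.0)
        params["comp_tau"] = max(params["comp_tau"], 0.0)
        params["comp_latency"] = max(params["comp_latency"], 100.0)
        params["adapt_retention"] = min(max(params["adapt_retention"], 0.0),
                                        0.995)
        params["noise_frame"] = max(params["noise_frame"], 0.0)
        params["noise_trial"] = max(params["noise_trial"], 0.0)
        params["age"] = float(rng.uniform(*config.age_range))
        group = "plus_first" if i % 2 == 0 else "minus_first"
        model = ParticipantModel(participant_id=pid, **params)
        models.append(model)
        rows.append({"participant_id": pid, "group": group, "age": model.age,
                     "f1_baseline": model.f1_baseline,
                     "trend_amplitude": model.trend_amplitude,
                     "trend_tau": model.trend_tau,
                     "g_mid": model.g_mid, "g_whole": model.g_whole,
                     "g_boost_mid": model.g_boost_mid,
                     "g_boost_whole": model.g_boost_whole,
                     "comp_latency": model.comp_latency,
                     "comp_tau": model.comp_tau,
                     "adapt_rate": model.adapt_rate,
                     "adapt_retention": model.adapt_retention,
                     "plateau_pct": model.plateau_pct,
                     "noise_frame": model.noise_frame,
                     "noise_trial": model.noise_trial})
    return models, pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


@dataclass
class CohortData:
    """A fully simulated cohort: schedules, tracks and ground truth."""

    config: CohortConfig
    participants: pd.DataFrame  # participant_id, group, age
    schedule: pd.DataFrame      # SCHEDULE_COLUMNS
    tracks: dict                # (participant_id, session, trial_index) -> FormantTrack
    ground_truth: pd.DataFrame
    true_states: pd.DataFrame   # participant_id, session, trial_index, state_hz


def simulate_cohort(config: CohortConfig,
                    sessions: tuple[int, ...] = (1, 2, 3, 4, 5)) -> CohortData:
    """Simulate a full cohort over the requested sessions."""
    from .design import schedule_to_frame  # avoid cycle at module import

    models, truth = draw_cohort_models(config)
    sched_frames, tracks, state_rows = [], {}, []
    for i, model in enumerate(models):
        pid = model.participant_id
        group = truth.loc[truth.participant_id == pid, "group"].iloc[0]
        sconf = replace(config.schedule, rng_seed=config.rng_seed,
                        counterbalance_group=group)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, 1,
                                    zlib.crc32(pid.encode())]))
        trial_lists: list[list[TrialSpec]] = []
        if any(s in sessions for s in (1, 3, 5)):
            unpred = [t for t in build_unpredictable_sessions(sconf, pid)
                      if t.session in sessions]
            trial_lists.append(unpred)
            for tr in simulate_unpredictable_sessions(
                    model, unpred, rng, config.trial_duration_ms,
                    config.frame_interval_ms):
                tracks[(pid, tr.session, tr.trial_index)] = tr
        for session in (2, 4):
            if session not in sessions:
                continue
            sched = build_adaptation_session(sconf, pid, session)
            trial_lists.append(sched)
            trs, states = simulate_adaptation_session(
                model, sched, rng, config.trial_duration_ms,
                config.frame_interval_ms)
            for tr, s in zip(trs, states):
                tracks[(pid, tr.session, tr.trial_index)] = tr
                state_rows.append({"participant_id": pid, "session": session,
                                   "trial_index": tr.trial_index,
                                   "state_hz": s})
        all_trials = [t for lst in trial_lists for t in lst]
        sched_frames.append(schedule_to_frame(all_trials, config.rng_seed))
        if config.p_exclude > 0:
            for t in all_trials:
                if t.word == "head" and rng.random() < config.p_exclude:
                    tracks[(pid, t.session, t.trial_index)].quality_flag = \
                        "excluded"

    schedule = pd.concat(sched_frames, ignore_index=True)
    participants = truth[["participant_id", "group", "age"]].copy()
    states = pd.DataFrame(state_rows, columns=["participant_id", "session",
                                               "trial_index", "state_hz"])
    return CohortData(config, participants, schedule, tracks, truth, states)
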